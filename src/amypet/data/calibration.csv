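tracer,reference,intercept,slope
PiB,WhlCbl,-94.64,93.75
PiB,CerebGry,-93.06,79.52
PiB,WhlCblBrnStm,-98.42,129.28
PiB,Pons,-95.58,99.68
florbetapir,WhlCbl,-182.23,175.17
flutemetamol,WhlCbl,-121.16,121.42
florbetaben,WhlCbl,-155.06,153.53
florbetaben,CerebGry,-152.93,128.95
florbetaben,WhlCblBrnStm,-156.65,217.92
florbetaben,Pons,-155.63,163.27
NAV4694,WhlCbl,-87.99,85.34
NAV4694,CerebGry,-86.21,71.70
NAV4694,WhlCblBrnStm,-93.44,122.27
NAV4694,Pons,-89.39,91.42
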