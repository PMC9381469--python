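level,slope,intercept,r2,n,threshold_osteopenia,threshold_osteoporosis
C2,1.253,90.15,0.5772,,240.5,190.4
C3,1.266,100.7,0.6282,,252.6,202.0
C4,1.350,101.2,0.6434,,263.2,209.2
C5,1.229,99.36,0.672,,246.8,197.7
C6,1.138,80.98,0.7504,,217.5,172.0
C7,0.9047,80.80,0.688,,189.4,153.2
T1,0.8606,54.50,0.7309,,157.8,123.3
T2,0.8758,48.93,0.7698,,154.0,119.0
T3,0.8591,39.86,0.7449,,143.0,108.6
T4,0.8295,36.64,0.7605,,136.2,103.0
T5,0.8132,34.69,0.7784,,132.3,99.7
T6,0.8190,31.52,0.7805,,129.8,97.0
T7,0.7929,32.59,0.7974,,127.7,96.0
T8,0.8113,29.22,0.8266,,126.6,94.1
T9,0.8357,28.50,0.8307,,128.8,95.4
T10,0.9000,23.01,0.874,,131.0,95.0
T11,0.9102,18.62,0.9069,,127.8,91.4
T12,0.9303,9.346,0.9268,,121.0,83.8
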