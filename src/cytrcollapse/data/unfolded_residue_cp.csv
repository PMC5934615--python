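residue,278.15,298.15,323.15,348.15,373.15
A,168.0,175.0,178.5,176.8,171.5
C,211.5,225.0,236.2,243.0,247.5
D,183.3,195.0,204.8,210.6,214.5
E,216.2,230.0,241.5,248.4,253.0
F,336.0,350.0,357.0,353.5,343.0
G,115.2,120.0,122.4,121.2,117.6
H,263.2,280.0,294.0,302.4,308.0
I,307.2,320.0,326.4,323.2,313.6
K,286.7,305.0,320.2,329.4,335.5
L,307.2,320.0,326.4,323.2,313.6
M,278.4,290.0,295.8,292.9,284.2
N,216.2,230.0,241.5,248.4,253.0
P,211.2,220.0,224.4,222.2,215.6
Q,249.1,265.0,278.2,286.2,291.5
R,314.9,335.0,351.8,361.8,368.5
S,159.8,170.0,178.5,183.6,187.0
T,202.1,215.0,225.8,232.2,236.5
V,268.8,280.0,285.6,282.8,274.4
W,384.0,400.0,408.0,404.0,392.0
Y,319.6,340.0,357.0,367.2,374.0
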