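# Default pharmacophore feature rules: one SMARTS list per feature class.
# D = H-bond donor, A = acceptor, H = hydrophobe, R = aromatic ring,
# N = negative ionizable, P = positive ionizable.  A feature is placed at
# the centroid of each (deduplicated) substructure match.
D:
  - "[#7;!H0]"
  - "[#8;!H0]"
  - "[#16;!H0]"
A:
  - "[N;X1,X2,X3;!+]"
  - "[O;X1,X2;!+]"
H:
  - "[C;H1,H2,H3;!$([C]~[#7,#8,#9,#15,#16,#17,#35,#53])]"
R:
  - "a1aaaaa1"
  - "a1aaaa1"
N:
  - "[CX3](=O)[OX1H0-,OX2H1]"
  - "[SX4](=O)(=O)[OX1H0-,OX2H1]"
  - "[PX4](=O)([OX1H0-,OX2H1])[OX1H0-,OX2H1]"
P:
  - "[NX3;H2,H3;+0;!$(NC=O)]"
  - "[N+]"
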