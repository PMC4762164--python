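trinucleotide	count
ACA	1071429
ACC	1071429
ACG	750000
ACT	1071429
ATA	1071429
ATC	1071429
ATG	1071429
ATT	1071429
CCA	1071429
CCC	1071429
CCG	750000
CCT	1071429
CTA	1071429
CTC	1071429
CTG	1071429
CTT	1071429
GCA	1071429
GCC	1071429
GCG	750000
GCT	1071429
GTA	1071429
GTC	1071429
GTG	1071429
GTT	1071429
TCA	1071429
TCC	1071429
TCG	750000
TCT	1071429
TTA	1071429
TTC	1071429
TTG	1071429
TTT	1071429
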