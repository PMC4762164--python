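trinucleotide	count
ACA	110732219
ACC	76949508
ACG	16928892
ACT	110732219
ATA	159346363
ATC	110732219
ATG	110732219
ATT	159346363
CCA	76949508
CCC	53473387
CCG	11764145
CCT	76949508
CTA	110732219
CTC	76949508
CTG	76949508
CTT	110732219
GCA	76949508
GCC	53473387
GCG	11764145
GCT	76949508
GTA	110732219
GTC	76949508
GTG	76949508
GTT	110732219
TCA	110732219
TCC	76949508
TCG	16928892
TCT	110732219
TTA	159346363
TTC	110732219
TTG	110732219
TTT	159346363
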