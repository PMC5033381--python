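→4)-β-D-Glcp-(1→4)-α-L-6dTalp-(1→4)-α-D-GalpA-(1→4)-α-D-Galp-(1→4)-[α-D-Glcp-(1→2)]-α-D-Galp-(1→
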