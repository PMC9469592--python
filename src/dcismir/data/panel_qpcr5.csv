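mirna_id,direction,provenance
miR-135a,down,age
miR-190b,down,age
miR-205,down,age
miR-30c,down,score
miR-744,down,score
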