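mirna_id,direction,provenance
miR-135b,up,score
miR-142-3p,up,score
miR-150-3p,up,score
miR-150,up,score
miR-155,up,score
miR-548b,up,score
miR-146a,up,score
miR-296-5p,up,score
miR-532-5p,up,score
miR-221,up,score
miR-193b-5p,down,score
miR-30c-1-3p,down,score
miR-193b,down,score
miR-744-3p,down,score
miR-744,down,score
miR-625-5p,down,score
miR-193a-5p,down,score
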