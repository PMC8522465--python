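kinship,group,exposed,total
ge1_relative,case,13,1620
ge1_relative,comparator,16,7797
any_first_degree,case,13,7615
any_first_degree,comparator,16,37309
parent,case,2,2306
parent,comparator,5,11414
full_sibling,case,9,2464
full_sibling,comparator,10,11685
offspring,case,2,2845
offspring,comparator,1,14210
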