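# Synthetic training structure set (curated toy structures, not from any
# structure database): one record per line, `name sequence structure`,
# dot-bracket with nested pairs only.  The set is small but covers every
# rule family of the folding grammar -- stacked helices, hairpins, left
# and right bulges, internal loops, three-, four- and five-way junctions,
# and external unpaired runs -- so that training-by-counting yields a
# usable default parameter set.  Replace via train_by_counting() on any
# larger annotated collection for serious use.
hp1 GGCGCGAAAGCGCC (((((....)))))
hp2 GCGGACUUCGGUCCGC ((((((....))))))
bl1 GGCAUGCACUUCGGUGCGCC (((..((((....)))))))
br1 GCGGGACGCAAGUCCACGC (((((((....)))).)))
il1 GCCGAAGGUCGAAAGACCGACGGC ((((..((((....))))..))))
il2 GGACUCGGUACGCCGAAGGUCC ((((.(((....)))...))))
j3a GCGACAAGGCGUGAGCCAGCGAUUCGUCGCCUGUCGC (((((..(((....))).((((....))))..)))))
j3b GGCAGGGAAACCCCGCCGCAAGGCAUUGCC (((((((....)))(((....)))..))))
j4a GGGCAGGCGAAAGCCUUGCGUUCGCGCGGACGUGAGUCCCGCCC ((((.(((....)))..(((....)))((((....)))).))))
jn1 GCGGAGGCGAAAGCCGCGUUCGCGCUGGACUUGUCCGACGCGAGUCAACCGC ((((.(((....)))(((....))).(((....)))(((....)))..))))
ext1 AAGGGCAGUUUCCUGCCAUCCGUGGAAACACGGCC ...(((((....)))))..(((((....)))))..
j3c GCCAGGGGCAGCAGGAAACUGCGCCUAGGGCUUCGGCCCCUGGC (((((.(((.((((....)))))))..((((....)))))))))
il3 GGGAUAGAGUCAGUAGGCGCGAGCCGAUGGACUCUAUCCC (((((.(((((....(((....)))....))))).)))))
hp3 GGGGCCAGCUUAUCGAACUGGCCCC ((((((((.........))))))))
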