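>U6 Homo sapiens U6 spliceosomal snRNA gene (106 nt)
GTGCTCGCTTCGGCAGCACATATACTAAAATTGGAACGATACAGAGAAGATTAGCATGGC
CCCTGCGCAAGGATGACACGCAAATTCGTGAAGCGTTCCATATTTT
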