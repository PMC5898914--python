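(mouse_lemur:0.090,(tarsier:0.080,(marmoset:0.055,(macaque:0.030,(gibbon:0.020,(orangutan:0.016,(gorilla:0.0085,((chimpanzee:0.0025,bonobo:0.0025)Pan:0.004,human:0.0065)Hominini:0.0020)Homininae:0.0075)Hominidae:0.0030)Hominoidae:0.0100)Catarrhini:0.0250)Simiiformes:0.0350)Haplorrhini:0.0400)root;
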