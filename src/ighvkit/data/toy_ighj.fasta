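>IGHJ1-1*01 anchor=12
CTAAGCCGAAAGTGGATCCCGTTCGCCTTCTCACACCTCGACAACCCT
>IGHJ2-1*01 anchor=12
CTAAGCCGAAAGTGGAGCACGTTAGCGCTCTTCCGCCTCTACAAGCCT
>IGHJ3-1*01 anchor=12
CTAAGCCGAAAGTGGATCACGTTCGCGTTCTTACGGCGCTGCGAACCT
>IGHJ4-1*01 anchor=12
CTAAGCCGAAAGTGGATCGCGTTCCCGTCCTTCCGTCTCTACAACCCT
>IGHJ5-1*01 anchor=12
CTAAGCCGAAAGTGGATCCCGTTCTCTTTCTTACGCCTCTGGAACCCT
>IGHJ6-1*01 anchor=12
CTAAGCCGAAAGTGGATCACGGTCAGGATCTTACACCTCTACAACCCT
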