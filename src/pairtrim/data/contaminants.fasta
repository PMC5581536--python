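>TruSeq Universal Adapter
AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT
>TruSeq Adapter, Read 1
AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
>TruSeq Adapter, Read 2
AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA
>Illumina Single End Adapter 1
GATCGGAAGAGCTCGTATGCCGTCTTCTGCTTG
>Illumina Single End PCR Primer 1
AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT
>Illumina Paired End Adapter 2
AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAG
>Illumina Small RNA 3' Adapter
TGGAATTCTCGGGTGCCAAGG
>Illumina Small RNA 5' Adapter
GTTCAGAGTTCTACAGTCCGACGATC
>Nextera Transposase Sequence
CTGTCTCTTATACACATCT
>Nextera Adapter Read 1
CTGTCTCTTATACACATCTCCGAGCCCACGAGAC
>Nextera Adapter Read 2
CTGTCTCTTATACACATCTGACGCTGCCGACGA
>Poly-A
AAAAAAAAAAAAAAAAAAAA
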