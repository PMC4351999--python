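set_name,forward_name,forward_seq,reverse_name,reverse_seq
1406f/23Sr,1406f,TGYACACACCGCCCGT,23Sr,GGGTTBCCCCATTCRG
ITSF/ITSReub,ITSF,GTCGTAACAAGGTAGCCGTA,ITSReub,GCCAAGGCATCCACC
S-D-Bact-1522-b-S-20/L-D-Bact-132-a-A-18,S-D-Bact-1522-b-S-20,TGCGGCTGGATCCCCTCCTT,L-D-Bact-132-a-A-18,CCGGGTTTCCCCATTCGG
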