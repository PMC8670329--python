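gene	chain	region	nt
TRBV2	beta	v_cdr3	TGCGCTAGCAGC
TRBV4-1	beta	v_cdr3	TGCGCTAGCCGT
TRBV5-1	beta	v_cdr3	TGCGCTAGCACC
TRBV6-1	beta	v_cdr3	TGCAGCGCTCGT
TRBV7-2	beta	v_cdr3	TGCGCTTGGAGC
TRBV9	beta	v_cdr3	TGCGCTAGCCAG
TRBV11-2	beta	v_cdr3	TGCGCTATTAGC
TRBV12-3	beta	v_cdr3	TGCAGCGTGGAA
TRBV15	beta	v_cdr3	TGCGCTAGCAGC
TRBV18	beta	v_cdr3	TGCGCTAGCCGT
TRBV19	beta	v_cdr3	TGCGCTAGCACC
TRBV20-1	beta	v_cdr3	TGCAGCGCTCGT
TRBV25-1	beta	v_cdr3	TGCGCTTGGAGC
TRBV27	beta	v_cdr3	TGCGCTAGCCAG
TRBV28	beta	v_cdr3	TGCGCTATTAGC
TRBV29-1	beta	v_cdr3	TGCAGCGTGGAA
TRBV30	beta	v_cdr3	TGCGCTAGCAGC
TRBJ1-1	beta	j_cdr3	AATACCGAAGCTTTCTTC
TRBJ1-2	beta	j_cdr3	AATTACGGTTACACCTTC
TRBJ1-4	beta	j_cdr3	AATGAAAAACTGTTCTTC
TRBJ1-5	beta	j_cdr3	AATCAGCCTCAGCATTTC
TRBJ1-6	beta	j_cdr3	AGCTACAATAGCCCTCTGCATTTC
TRBJ2-1	beta	j_cdr3	AGCTACAATGAACAGTTCTTC
TRBJ2-2	beta	j_cdr3	AATACCGGTGAACTGTTCTTC
TRBJ2-3	beta	j_cdr3	AGCACCGATACCCAGTACTTC
TRBJ2-4	beta	j_cdr3	GCTAAAAATATTCAGTACTTC
TRBJ2-5	beta	j_cdr3	CAGGAAACCCAGTACTTC
TRBJ2-7	beta	j_cdr3	AGCAGCTACGAACAGTACTTC
TRAV1-2	alpha	v_cdr3	TGCGCTGTGCGT
TRAV3	alpha	v_cdr3	TGCGCTGGTGGT
TRAV8-1	alpha	v_cdr3	TGCGCTATG
TRAV9-2	alpha	v_cdr3	TGCATTGTG
TRAV12-1	alpha	v_cdr3	TGCGCTCTGAGC
TRAV13-1	alpha	v_cdr3	TGCGCTGAA
TRAV17	alpha	v_cdr3	TGCGCTTTC
TRAV19	alpha	v_cdr3	TGCGCTACC
TRAV21	alpha	v_cdr3	TGCGCTGTGCGT
TRAV22	alpha	v_cdr3	TGCGCTGGTGGT
TRAV26-1	alpha	v_cdr3	TGCGCTATG
TRAV27	alpha	v_cdr3	TGCATTGTG
TRAV29	alpha	v_cdr3	TGCGCTCTGAGC
TRAV35	alpha	v_cdr3	TGCGCTGAA
TRAV38-1	alpha	v_cdr3	TGCGCTTTC
TRAV41	alpha	v_cdr3	TGCGCTACC
TRAJ4	alpha	j_cdr3	GGTGGTTACAATAAACTGATTTTC
TRAJ9	alpha	j_cdr3	ACCGGTGGTTTCAAAACCATTTTC
TRAJ12	alpha	j_cdr3	ATGGATAGCAGCTACAAACTGATTTTC
TRAJ20	alpha	j_cdr3	AATGATTACAAACTGAGCTTC
TRAJ23	alpha	j_cdr3	TACAATCAGGGTGGTAAACTGATTTTC
TRAJ30	alpha	j_cdr3	AATCGTGATGATAAAATTATTTTC
TRAJ33	alpha	j_cdr3	GATAGCAATTACCAGCTGATTTGG
TRAJ42	alpha	j_cdr3	GGTAGCCAGGGTAATCTGATTTTC
TRAJ45	alpha	j_cdr3	GGTGGTGGTGCTGATGGTCTGACCTTC
TRAJ49	alpha	j_cdr3	AATACCGGTAATCAGTTCTACTTC
TRBD1	beta	d_seg	GGGACAGGGGGC
TRBD2	beta	d_seg	GGGACTAGCGGGGGG
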