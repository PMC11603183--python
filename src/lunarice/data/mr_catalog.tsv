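gene_id	name	description	mechanism
Os01g0275600	AGO4a	Argonaute protein	RdDM
Os07g0182900	MET1b	DNA methyltransferase, CG site maintenance methylation	CG maintenance
Os04g0465700	RDR2	RNA-dependent RNA polymerase 2	RdDM
Os01g0527600	RDR6	RNA-dependent RNA polymerase 6	RdDM
Os05g0445900	ROS1c	DNA demethylase	demethylation
Os12g0607000	HMT	Homocysteine S-methyltransferase 2	RdDM
Os10g0577600	JMJ706	H3K9 demethylase	RdDM
Os11g0602200	SDG704	Histone methyltransferase	RdDM
Os09g0307800	SDG724	Histone methyltransferase	RdDM
Os02g0554000	SDG725	Histone H3K36 methyltransferase	RdDM
Os07g0435900	SDG726	Histone H3K9 methyltransferase	RdDM
Os05g0490700	SDG728	Histone H3K9 methyltransferase	RdDM
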