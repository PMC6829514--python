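# Synthetic demo catalogue of activity-annotated short peptides.
# Sequences are di-/tripeptides of the kind reported in the food-protein
# bioactive-peptide literature, assembled here as a self-contained test and
# demo fixture. This file is NOT a copy of the BIOPEP-UWM database or of any
# other hosted catalogue; absolute counts computed against it are not
# comparable with counts published against such databases.
# Columns: id, sequence, activity, reference
id	sequence	activity	reference
D0001	AE	DPP-IV inhibitor	demo fixture
D0002	GP	DPP-IV inhibitor	demo fixture
D0003	PG	DPP-IV inhibitor	demo fixture
D0004	VA	DPP-IV inhibitor	demo fixture
D0005	IP	DPP-IV inhibitor	demo fixture
D0006	VP	DPP-IV inhibitor	demo fixture
D0007	LP	DPP-IV inhibitor	demo fixture
D0008	FP	DPP-IV inhibitor	demo fixture
D0009	WV	DPP-IV inhibitor	demo fixture
D0010	WP	DPP-IV inhibitor	demo fixture
D0011	IPI	DPP-IV inhibitor	demo fixture
D0012	GA	DPP-IV inhibitor	demo fixture
D0013	AP	DPP-IV inhibitor	demo fixture
D0014	KA	DPP-IV inhibitor	demo fixture
D0015	MP	DPP-IV inhibitor	demo fixture
D0016	HP	DPP-IV inhibitor	demo fixture
D0017	YP	DPP-IV inhibitor	demo fixture
D0018	RP	DPP-IV inhibitor	demo fixture
D0019	TP	DPP-IV inhibitor	demo fixture
D0020	SP	DPP-IV inhibitor	demo fixture
D0021	NP	DPP-IV inhibitor	demo fixture
D0022	QP	DPP-IV inhibitor	demo fixture
D0023	EP	DPP-IV inhibitor	demo fixture
D0024	DP	DPP-IV inhibitor	demo fixture
D0025	PP	DPP-IV inhibitor	demo fixture
D0026	GL	DPP-IV inhibitor	demo fixture
D0027	AL	DPP-IV inhibitor	demo fixture
D0028	VL	DPP-IV inhibitor	demo fixture
D0029	WA	DPP-IV inhibitor	demo fixture
D0030	WL	DPP-IV inhibitor	demo fixture
D0031	WI	DPP-IV inhibitor	demo fixture
D0032	PL	DPP-IV inhibitor	demo fixture
D0033	PA	DPP-IV inhibitor	demo fixture
D0034	VPL	DPP-IV inhibitor	demo fixture
D0035	LPL	DPP-IV inhibitor	demo fixture
D0036	GPG	DPP-IV inhibitor	demo fixture
D0037	GPA	DPP-IV inhibitor	demo fixture
D0038	LPQ	DPP-IV inhibitor	demo fixture
D0039	IPA	DPP-IV inhibitor	demo fixture
D0040	APG	DPP-IV inhibitor	demo fixture
D0041	ML	DPP-IV inhibitor	demo fixture
D0042	HL	DPP-IV inhibitor	demo fixture
D0043	AI	DPP-IV inhibitor	demo fixture
D0044	VI	DPP-IV inhibitor	demo fixture
D0045	TA	DPP-IV inhibitor	demo fixture
A0001	EA	ACE inhibitor	demo fixture
A0002	VY	ACE inhibitor	demo fixture
A0003	IY	ACE inhibitor	demo fixture
A0004	AW	ACE inhibitor	demo fixture
A0005	VW	ACE inhibitor	demo fixture
A0006	IW	ACE inhibitor	demo fixture
A0007	LW	ACE inhibitor	demo fixture
A0008	KW	ACE inhibitor	demo fixture
A0009	RW	ACE inhibitor	demo fixture
A0010	GY	ACE inhibitor	demo fixture
A0011	AY	ACE inhibitor	demo fixture
A0012	LY	ACE inhibitor	demo fixture
A0013	RY	ACE inhibitor	demo fixture
A0014	HY	ACE inhibitor	demo fixture
A0015	KY	ACE inhibitor	demo fixture
A0016	FY	ACE inhibitor	demo fixture
A0017	AF	ACE inhibitor	demo fixture
A0018	VF	ACE inhibitor	demo fixture
A0019	IF	ACE inhibitor	demo fixture
A0020	GF	ACE inhibitor	demo fixture
A0021	YP	ACE inhibitor	demo fixture
A0022	RF	ACE inhibitor	demo fixture
A0023	KF	ACE inhibitor	demo fixture
A0024	EF	ACE inhibitor	demo fixture
A0025	DF	ACE inhibitor	demo fixture
A0026	EW	ACE inhibitor	demo fixture
A0027	DW	ACE inhibitor	demo fixture
A0028	EY	ACE inhibitor	demo fixture
A0029	DY	ACE inhibitor	demo fixture
A0030	SY	ACE inhibitor	demo fixture
A0031	TY	ACE inhibitor	demo fixture
A0032	NY	ACE inhibitor	demo fixture
A0033	QY	ACE inhibitor	demo fixture
A0034	MY	ACE inhibitor	demo fixture
A0035	GE	ACE inhibitor	demo fixture
A0036	IPP	ACE inhibitor	demo fixture
A0037	VPP	ACE inhibitor	demo fixture
A0038	LKP	ACE inhibitor	demo fixture
A0039	IKP	ACE inhibitor	demo fixture
A0040	LRP	ACE inhibitor	demo fixture
A0041	IRP	ACE inhibitor	demo fixture
A0042	GKP	ACE inhibitor	demo fixture
A0043	AKK	ACE inhibitor	demo fixture
A0044	VAP	ACE inhibitor	demo fixture
A0045	FQP	ACE inhibitor	demo fixture
A0046	LQP	ACE inhibitor	demo fixture
A0047	IQP	ACE inhibitor	demo fixture
A0048	LLP	ACE inhibitor	demo fixture
A0049	GPL	ACE inhibitor	demo fixture
A0050	GPV	ACE inhibitor	demo fixture
A0051	IVY	ACE inhibitor	demo fixture
A0052	LVY	ACE inhibitor	demo fixture
A0053	IVW	ACE inhibitor	demo fixture
A0054	LVW	ACE inhibitor	demo fixture
A0055	VIY	ACE inhibitor	demo fixture
A0056	VVY	ACE inhibitor	demo fixture
A0057	YL	ACE inhibitor	demo fixture
A0058	YV	ACE inhibitor	demo fixture
A0059	WF	ACE inhibitor	demo fixture
A0060	FL	ACE inhibitor	demo fixture
O0001	LQ	antioxidative	demo fixture
O0002	EL	antioxidative	demo fixture
O0003	HH	antioxidative	demo fixture
O0004	YG	antioxidative	demo fixture
O0005	AH	antioxidative	demo fixture
O0006	LH	antioxidative	demo fixture
O0007	IR	antithrombotic	demo fixture
O0008	GQ	antithrombotic	demo fixture
O0009	PQ	antiamnestic	demo fixture
O0010	QP	antiamnestic	demo fixture
O0011	GR	renin inhibitor	demo fixture
O0012	IE	renin inhibitor	demo fixture
O0013	GQR	immunomodulating	demo fixture
O0014	EAE	immunomodulating	demo fixture
O0015	YG	neuropeptide	demo fixture
O0016	GK	stimulating	demo fixture
O0017	EE	regulating	demo fixture
O0018	SD	alpha glucosidase inhibitor	demo fixture
O0019	LK	activating ubiquitin-mediated proteolysis	demo fixture
O0020	AK	activating ubiquitin-mediated proteolysis	demo fixture
O0021	KE	antibacterial	demo fixture
O0022	HK	antibacterial	demo fixture
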