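strain_id	gene	category
WT	YDL227C	wildtype_control
can1Δ	CAN1	transporter_mutant
nrt1Δ	NRT1	transporter_mutant
fcy2Δ	FCY2	transporter_mutant
fen2Δ	FEN2	transporter_mutant
ctr1Δ	CTR1	transporter_mutant
fui1Δ	FUI1	transporter_mutant
agp1Δ	AGP1	transporter_mutant
mal11Δ	MAL11	transporter_mutant
itr1Δ	ITR1	transporter_mutant
fat1Δ	FAT1	transporter_mutant
lem3Δ	LEM3	transporter_mutant
dnf2Δ	DNF2	transporter_mutant
qdr2Δ	QDR2	transporter_mutant
pca1Δ	PCA1	transporter_mutant
pho89Δ	PHO89	transporter_mutant
snq2Δ	SNQ2	transporter_mutant
cch1Δ	CCH1	transporter_mutant
mid1Δ	MID1	transporter_mutant
fps1Δ	FPS1	transporter_mutant
hnm1Δ	HNM1	transporter_mutant
pdr5Δ	PDR5	transporter_mutant
fet3Δ	FET3	transporter_mutant
ftr1Δ	FTR1	transporter_mutant
pug1Δ	PUG1	transporter_mutant
vht1Δ	VHT1	transporter_mutant
ypp1Δ	YPP1	transporter_mutant
alr1Δ	ALR1	transporter_mutant
ste6Δ	STE6	transporter_mutant
dal5Δ	DAL5	transporter_mutant
hxt1Δ	HXT1	transporter_mutant
hxt2Δ	HXT2	transporter_mutant
hxt3Δ	HXT3	transporter_mutant
hxt4Δ	HXT4	transporter_mutant
hxt5Δ	HXT5	transporter_mutant
hxt6Δ	HXT6	transporter_mutant
hxt7Δ	HXT7	transporter_mutant
hxt8Δ	HXT8	transporter_mutant
hxt9Δ	HXT9	transporter_mutant
hxt11Δ	HXT11	transporter_mutant
hxt13Δ	HXT13	transporter_mutant
gal2Δ	GAL2	transporter_mutant
stl1Δ	STL1	transporter_mutant
jen1Δ	JEN1	transporter_mutant
ady2Δ	ADY2	transporter_mutant
ato2Δ	ATO2	transporter_mutant
ato3Δ	ATO3	transporter_mutant
gap1Δ	GAP1	transporter_mutant
put4Δ	PUT4	transporter_mutant
lyp1Δ	LYP1	transporter_mutant
alp1Δ	ALP1	transporter_mutant
dip5Δ	DIP5	transporter_mutant
bap2Δ	BAP2	transporter_mutant
bap3Δ	BAP3	transporter_mutant
tat1Δ	TAT1	transporter_mutant
tat2Δ	TAT2	transporter_mutant
gnp1Δ	GNP1	transporter_mutant
agp2Δ	AGP2	transporter_mutant
agp3Δ	AGP3	transporter_mutant
mmp1Δ	MMP1	transporter_mutant
sam3Δ	SAM3	transporter_mutant
mup1Δ	MUP1	transporter_mutant
mup3Δ	MUP3	transporter_mutant
uga4Δ	UGA4	transporter_mutant
dur3Δ	DUR3	transporter_mutant
mep1Δ	MEP1	transporter_mutant
mep2Δ	MEP2	transporter_mutant
mep3Δ	MEP3	transporter_mutant
pho84Δ	PHO84	transporter_mutant
pho87Δ	PHO87	transporter_mutant
sul1Δ	SUL1	transporter_mutant
sul2Δ	SUL2	transporter_mutant
zrt1Δ	ZRT1	transporter_mutant
zrt2Δ	ZRT2	transporter_mutant
fet4Δ	FET4	transporter_mutant
smf1Δ	SMF1	transporter_mutant
smf2Δ	SMF2	transporter_mutant
ctr3Δ	CTR3	transporter_mutant
sit1Δ	SIT1	transporter_mutant
arn1Δ	ARN1	transporter_mutant
ena1Δ	ENA1	transporter_mutant
ena2Δ	ENA2	transporter_mutant
nha1Δ	NHA1	transporter_mutant
trk1Δ	TRK1	transporter_mutant
trk2Δ	TRK2	transporter_mutant
tok1Δ	TOK1	transporter_mutant
pma1Δ	PMA1	transporter_mutant
pdr12Δ	PDR12	transporter_mutant
yor1Δ	YOR1	transporter_mutant
aqr1Δ	AQR1	transporter_mutant
flr1Δ	FLR1	transporter_mutant
dtr1Δ	DTR1	transporter_mutant
azr1Δ	AZR1	transporter_mutant
sge1Δ	SGE1	transporter_mutant
tpo1Δ	TPO1	transporter_mutant
tpo2Δ	TPO2	transporter_mutant
tpo3Δ	TPO3	transporter_mutant
aqy1Δ	AQY1	transporter_mutant
aqy2Δ	AQY2	transporter_mutant
fur4Δ	FUR4	transporter_mutant
thi7Δ	THI7	transporter_mutant
thi72Δ	THI72	transporter_mutant
tpn1Δ	TPN1	transporter_mutant
ptr2Δ	PTR2	transporter_mutant
opt1Δ	OPT1	transporter_mutant
opt2Δ	OPT2	transporter_mutant
seo1Δ	SEO1	transporter_mutant
ssu1Δ	SSU1	transporter_mutant
dal4Δ	DAL4	transporter_mutant
bio5Δ	BIO5	transporter_mutant
itr2Δ	ITR2	transporter_mutant
fcy21Δ	FCY21	transporter_mutant
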