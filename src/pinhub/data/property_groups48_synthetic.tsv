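# Default physicochemical property table: 48 named residue groups.
# SYNTHETIC STAND-IN: assembled from standard amino-acid classification
# schemes (hydrophobicity / volume / polarity / polarizability / charge /
# secondary-structure / accessibility triples plus classic binary groups);
# it is not the original 48-property list, which is not publicly tabulated.
# The aromatic group (H, F, W, Y) is definitional.
# Format: group_name TAB residue letters.
hydrophobicity_polar	RKEDQN
hydrophobicity_neutral	GASTPHY
hydrophobicity_hydrophobic	CLVIMFW
volume_small	GASCTPD
volume_medium	NVEQIL
volume_large	MHKFRYW
polarity_low	LIFWCMVY
polarity_medium	PATGS
polarity_high	HQRKNED
polarizability_low	GASDT
polarizability_medium	CPNVEQIL
polarizability_high	KMHFRYW
charge_positive	KR
charge_neutral	ANCQGHILMFPSTWYV
charge_negative	DE
helix_preferring	EALMQKRH
strand_preferring	VIYCWFT
coil_preferring	GNPSD
buried	ALFCGIVW
exposed	RKQEND
intermediate_accessibility	MSPTHY
aromatic	HFWY
aliphatic	ILV
tiny	AGCS
small	ACDGNPSTV
bulky	FHRWY
basic	HKR
acidic_amide	DENQ
charged	DEHKR
polar_uncharged	CNQSTY
hydroxylic	STY
sulfur_containing	CM
amide	NQ
imino	P
helix_breaker	GP
disorder_promoting	ARSQEGKP
order_promoting	NCILFWYV
flexible	DEGKNPQS
rigid	CFILMVWY
surface_preferring	DEGHKNPQRSTY
interior_preferring	ACFILMVW
hbond_donor	HKNQRSTWY
hbond_acceptor	DEHNQSTY
high_mass	FHKMRWY
low_mass	ACDGNST
turn_preferring	DGNPS
aromatic_nonpolar	FW
beta_branched	ITV
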