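# Synthetic stand-in for the NeuroMark fMRI 1.0 component->network assignment:
# 53 independent components grouped into 7 functional networks with the
# published network sizes (SCN 5, AUD 2, SMN 9, VSN 9, CCN 17, DMN 7, CBN 4).
# Component ids are generic placeholders, not anatomical labels.
component	network
IC01	SCN
IC02	SCN
IC03	SCN
IC04	SCN
IC05	SCN
IC06	AUD
IC07	AUD
IC08	SMN
IC09	SMN
IC10	SMN
IC11	SMN
IC12	SMN
IC13	SMN
IC14	SMN
IC15	SMN
IC16	SMN
IC17	VSN
IC18	VSN
IC19	VSN
IC20	VSN
IC21	VSN
IC22	VSN
IC23	VSN
IC24	VSN
IC25	VSN
IC26	CCN
IC27	CCN
IC28	CCN
IC29	CCN
IC30	CCN
IC31	CCN
IC32	CCN
IC33	CCN
IC34	CCN
IC35	CCN
IC36	CCN
IC37	CCN
IC38	CCN
IC39	CCN
IC40	CCN
IC41	CCN
IC42	CCN
IC43	DMN
IC44	DMN
IC45	DMN
IC46	DMN
IC47	DMN
IC48	DMN
IC49	DMN
IC50	CBN
IC51	CBN
IC52	CBN
IC53	CBN
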