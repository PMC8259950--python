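# Curated gene catalog: how an expression deficit or excess of each human
# gene acts on rheumatoid arthritis (aggravate = contributes, relieve =
# protects). Covers the ortholog-comparison genes plus MMP12.
gene	category	deficit_effect	excess_effect	note
MMP12	comorbid_clinical	relieve	aggravate	macrophage elastase; underexpression accompanies reduced asthma and RA risk
ESR2	comorbid_clinical	aggravate	relieve	estrogen receptor beta; less ESR2-dependent suppression of inflammation on deficit
IL1R2	immunosuppressive	aggravate	relieve	decoy IL-1 receptor; silencing supports inflammation
IL9R	immunostimulatory	relieve	aggravate	interleukin-9 receptor; excess drives synoviocyte proliferation
NPY	ra_associated	relieve	aggravate	neuropeptide Y; excess raises obesity-linked RA risk
TGFB2	immunosuppressive	relieve	aggravate	TGF-beta 2; excess inhibits bone repair in inflamed joints
F7	comorbid_clinical	aggravate	relieve	coagulation factor VII; deficit raises hemorrhagic complications
CCR6	ra_associated	relieve	aggravate	chemokine receptor 6; deficit reduces autoimmunity
CETP	comorbid_clinical	aggravate	aggravate	lipid transfer protein; both deficit (mortality) and excess (risk) harmful
IL1B	comorbid_clinical	relieve	aggravate	interleukin-1 beta; excess linked to circadian pain
PDYN	comorbid_clinical	aggravate	relieve	prodynorphin; excess raises pain resistance
HBB	comorbid_clinical	aggravate	aggravate	beta-globin; both thalassemic deficit and hemolytic excess harmful
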