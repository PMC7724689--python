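herb_latin	herb_pinyin	name	compound_id	mass_da	mass_mode	formula
Radix Scrophulariae	XuanShen	Sugiol	84979	300.435	average	C_20_H_28_O_2_
Radix Scrophulariae	XuanShen	β-Sitosterol	192962	414.386	monoisotopic	C_29_H_50_O
Radix Scrophulariae	XuanShen	Sitosterol	192962	414.386	monoisotopic	C_29_H_50_O
Bulbus Fritillariae Ferganensis	ZheBeiMu	β-Sitosterol	192962	414.386	monoisotopic	C_29_H_50_O
Bulbus Fritillariae Ferganensis	ZheBeiMu	Zhebeiresinol	4474746	280.273	average	C_14_H_16_O_6_
Concha Ostreae	ShengMuLi	Aluminum	4514248	26.982	average	Al
Concha Ostreae	ShengMuLi	Calcium carbonate	9708	100.087	average	CCaO_3_
Concha Ostreae	ShengMuLi	Calcium phosphate	22864	310.177	average	Ca_3_O_8_P_2_
Concha Ostreae	ShengMuLi	Calcium sulphate	22905	136.141	average	CaO_4_S
Concha Ostreae	ShengMuLi	Silicon	4574465	28.086	average	Si
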