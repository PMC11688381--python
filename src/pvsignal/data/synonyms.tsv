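variant	ingredient
GEMZAR	GEMCITABINE
ACETAMINOPHEN	PARACETAMOL
TYLENOL	PARACETAMOL
ADVIL	IBUPROFEN
MOTRIN	IBUPROFEN
CYCLOSPORINE	CICLOSPORIN
CYCLOSPORIN	CICLOSPORIN
NEORAL	CICLOSPORIN
SANDIMMUNE	CICLOSPORIN
PROGRAF	TACROLIMUS
FK506	TACROLIMUS
CELLCEPT	MYCOPHENOLATE MOFETIL
SOLIRIS	ECULIZUMAB
THYMOGLOBULIN	ANTI-THYMOCYTE GLOBULIN
ANTITHYMOCYTE GLOBULIN	ANTI-THYMOCYTE GLOBULIN
NUVARING	ETONOGESTREL AND ETHINYLESTRADIOL VAGINAL RING
ETONOGESTREL AND ETHINYLESTRADIOL	ETONOGESTREL AND ETHINYLESTRADIOL VAGINAL RING
AVASTIN	BEVACIZUMAB
PARAPLATIN	CARBOPLATIN
SUTENT	SUNITINIB
OPDIVO	NIVOLUMAB
KEYTRUDA	PEMBROLIZUMAB
XELODA	CAPECITABINE
GLUCOPHAGE	METFORMIN
CIPRO	CIPROFLOXACIN
LAMICTAL	LAMOTRIGINE
RITUXAN	RITUXIMAB
REMICADE	INFLIXIMAB
COUMADIN	WARFARIN
JANTOVEN	WARFARIN
LOVENOX	ENOXAPARIN
PLAVIX	CLOPIDOGREL
XARELTO	RIVAROXABAN
ELIQUIS	APIXABAN
PRADAXA	DABIGATRAN ETEXILATE
ASA	ACETYLSALICYLIC ACID
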