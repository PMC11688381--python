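ingredient	atc_class
GEMCITABINE	antineoplastic agents
BUSULFAN	antineoplastic agents
CYCLOPHOSPHAMIDE	antineoplastic agents
BEVACIZUMAB	antineoplastic agents
CARBOPLATIN	antineoplastic agents
SUNITINIB	antineoplastic agents
CYTARABINE	antineoplastic agents
NIVOLUMAB	antineoplastic agents
PEMBROLIZUMAB	antineoplastic agents
CAPECITABINE	antineoplastic agents
METHOTREXATE	antineoplastic agents
RITUXIMAB	antineoplastic agents
TACROLIMUS	immunosuppressants
CICLOSPORIN	immunosuppressants
MYCOPHENOLATE MOFETIL	immunosuppressants
ECULIZUMAB	immunosuppressants
ANTI-THYMOCYTE GLOBULIN	immunosuppressants
INFLIXIMAB	immunosuppressants
PARACETAMOL	analgesics
IBUPROFEN	analgesics
PREDNISOLONE	corticosteroids for systemic use
DEXAMETHASONE	corticosteroids for systemic use
ETONOGESTREL AND ETHINYLESTRADIOL VAGINAL RING	sex hormones and modulators of the genital system
LAMOTRIGINE	antiepileptics
METFORMIN	drugs used in diabetes
CIPROFLOXACIN	antibacterials for systemic use
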