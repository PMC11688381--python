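pt_name	pt_code	weight
Coagulopathy	10009802	15057
Disseminated intravascular coagulation	10013442	12954
Thrombotic microangiopathy	10079988	8050
Hypercoagulation	10020608	1771
Antiphospholipid syndrome	10002817	1395
Factor VIII inhibition	10048619	1007
Hypocoagulable state	10020973	861
Abnormal clotting factor	10049862	198
Factor V inhibition	10056335	180
Factor IX inhibition	10051778	127
Heparin resistance	10059598	93
Hyperfibrinogenaemia	10051124	61
Coagulation disorder neonatal	10009732	55
Hyperfibrinolysis	10074737	52
Activated protein C resistance	10067648	33
Von Willebrand's factor inhibition	10070690	30
Factor XIII inhibition	10059608	27
Disseminated intravascular coagulation in newborn	10013443	25
Factor VII inhibition	10075240	16
Acquired dysfibrinogenaemia	10051122	7
Lupus anticoagulant hypoprothrombinaemia syndrome	10085219	4
Hyperprothrombinaemia	10067920	3
Hyperthrombinaemia	10058516	3
Factor II inhibition	10075242	2
Factor X inhibition	10075241	1
Pseudo-heparin resistance	10088924	1
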