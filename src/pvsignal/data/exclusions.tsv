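ingredient	category
HEPARIN	anticoagulant (unfractionated heparin)
ENOXAPARIN	anticoagulant (low-molecular-weight heparin)
DALTEPARIN	anticoagulant (low-molecular-weight heparin)
TINZAPARIN	anticoagulant (low-molecular-weight heparin)
NADROPARIN	anticoagulant (low-molecular-weight heparin)
FONDAPARINUX	anticoagulant (factor Xa inhibitor, parenteral)
WARFARIN	anticoagulant (vitamin K antagonist)
ACENOCOUMAROL	anticoagulant (vitamin K antagonist)
PHENPROCOUMON	anticoagulant (vitamin K antagonist)
RIVAROXABAN	anticoagulant (direct oral factor Xa inhibitor)
APIXABAN	anticoagulant (direct oral factor Xa inhibitor)
EDOXABAN	anticoagulant (direct oral factor Xa inhibitor)
BETRIXABAN	anticoagulant (direct oral factor Xa inhibitor)
DABIGATRAN ETEXILATE	anticoagulant (direct thrombin inhibitor)
ARGATROBAN	anticoagulant (direct thrombin inhibitor)
BIVALIRUDIN	anticoagulant (direct thrombin inhibitor)
CLOPIDOGREL	antiplatelet (P2Y12 inhibitor)
PRASUGREL	antiplatelet (P2Y12 inhibitor)
TICAGRELOR	antiplatelet (P2Y12 inhibitor)
TICLOPIDINE	antiplatelet (P2Y12 inhibitor)
CANGRELOR	antiplatelet (P2Y12 inhibitor)
ASPIRIN	antiplatelet (COX inhibitor)
ACETYLSALICYLIC ACID	antiplatelet (COX inhibitor)
DIPYRIDAMOLE	antiplatelet (phosphodiesterase inhibitor)
CILOSTAZOL	antiplatelet (phosphodiesterase inhibitor)
ABCIXIMAB	antiplatelet (GPIIb/IIIa inhibitor)
EPTIFIBATIDE	antiplatelet (GPIIb/IIIa inhibitor)
TIROFIBAN	antiplatelet (GPIIb/IIIa inhibitor)
VORAPAXAR	antiplatelet (PAR-1 antagonist)
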