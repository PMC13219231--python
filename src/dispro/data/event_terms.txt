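Fournier's gangrene
Cellulitis gangrenous
Diabetic gangrene
Gas gangrene
Dry gangrene
Amputation
Leg amputation
Foot amputation
Limb amputation
Toe amputation
Diabetic foot
Osteomyelitis
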