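endpoint,substance,cas,in_vitro,structure_based,qsar
PPARG_INACTIVATION,Cetylpyridinium chloride,123-03-5,Positive,Positive,Negative
PPARG_INACTIVATION,Cyfluthrin,68359-37-5,Negative,Positive,Negative
PPARG_INACTIVATION,Deltamethrin,52918-63-5,Negative,Positive,Negative
PPARG_INACTIVATION,Muscalure,27519-02-4,Negative,Positive,Negative
PPARG_INACTIVATION,Piperonyl butoxide,51-03-6,Negative,Positive,Negative
TLR4_ACTIVATION,Propetamphos,31218-83-4,Negative,Positive,Negative
TLR4_ACTIVATION,Prallethrin,23031-36-9,Negative,Positive,Negative
TLR4_ACTIVATION,Novaluron,116714-46-6,Negative,Positive,Negative
TLR4_ACTIVATION,Imiprothrin,72963-72-5,Negative,Positive,Negative
TLR4_ACTIVATION,Dinotefuran,165252-70-0,Positive,Negative,Positive
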