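>FOX_LIKE FOX_LIKE
A [  1  1  1  1  1 97  1 ]
C [  1  1  1  1  1  1 97 ]
G [  1 97  1  1  1  1  1 ]
T [ 97  1 97 97 97  1  1 ]
>ERE_HALF ERE_HALF
A [ 97  1  1  1  1 97 ]
C [  1  1  1  1 97  1 ]
G [  1 97 97  1  1  1 ]
T [  1  1  1 97  1  1 ]
>AP1_LIKE AP1_LIKE
A [  1  1 97  1  1  1 97 ]
C [  1  1  1 97  1 97  1 ]
G [  1 97  1  1  1  1  1 ]
T [ 97  1  1  1 97  1  1 ]
>NHR_LIKE NHR_LIKE
A [  1  1  1  1  1 97 ]
C [  1  1  1  1 97  1 ]
G [  1 97 97  1  1  1 ]
T [ 97  1  1 97  1  1 ]
>GATA_LIKE GATA_LIKE
A [ 97  1 97  1 97 97 ]
C [  1  1  1  1  1  1 ]
G [  1 97  1  1  1  1 ]
T [  1  1  1 97  1  1 ]
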