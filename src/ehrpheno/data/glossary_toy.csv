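code,category
C2675043,social_interaction
C0557875,social_interaction
C0454644,social_interaction
C0233514,social_interaction
C0020796,social_interaction
C0917801,social_interaction
C0424092,social_interaction
C0558141,social_interaction
CHIP1000101,social_interaction
CHIP1000102,social_interaction
CHIP1000103,social_interaction
CHIP1000104,social_interaction
CHIP1000105,social_interaction
CHIP1000106,social_interaction
CHIP1000107,social_interaction
CHIP1000108,social_interaction
C0454643,communication
C0233715,communication
C0241210,communication
C0576908,communication
C0699744,communication
CHIP1000201,communication
CHIP1000202,communication
CHIP1000203,communication
CHIP1000204,communication
CHIP1000205,communication
C0233650,behavior
C0085271,behavior
C0233730,behavior
C0424295,behavior
C0557874,behavior
C0236018,behavior
C0424230,behavior
CHIP1000301,behavior
CHIP1000302,behavior
CHIP1000303,behavior
CHIP1000304,behavior
CHIP1000305,behavior
CHIP1000306,behavior
CHIP1000307,behavior
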