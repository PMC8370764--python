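strain	axis	segment
SJL	TRBV	TRBV1
SJL	TRBV	TRBV2
SJL	TRBV	TRBV3
SJL	TRBV	TRBV4
SJL	TRBV	TRBV5
SJL	TRBV	TRBV19
SJL	TRBV	TRBV20
SJL	TRBV	TRBV23
SJL	TRBV	TRBV24
SJL	TRBV	TRBV26
SJL	TRBV	TRBV29
SJL	TRBV	TRBV31
SJL	TRBJ	TRBJ1-1
SJL	TRBJ	TRBJ1-2
SJL	TRBJ	TRBJ1-3
SJL	TRBJ	TRBJ1-4
SJL	TRBJ	TRBJ1-5
SJL	TRBJ	TRBJ2-1
SJL	TRBJ	TRBJ2-2
SJL	TRBJ	TRBJ2-3
SJL	TRBJ	TRBJ2-4
SJL	TRBJ	TRBJ2-5
SJL	TRBJ	TRBJ2-7
B6s	TRBV	TRBV1
B6s	TRBV	TRBV2
B6s	TRBV	TRBV3
B6s	TRBV	TRBV4
B6s	TRBV	TRBV5
B6s	TRBV	TRBV12-1
B6s	TRBV	TRBV12-2
B6s	TRBV	TRBV13-1
B6s	TRBV	TRBV13-2
B6s	TRBV	TRBV13-3
B6s	TRBV	TRBV14
B6s	TRBV	TRBV15
B6s	TRBV	TRBV16
B6s	TRBV	TRBV17
B6s	TRBV	TRBV19
B6s	TRBV	TRBV20
B6s	TRBV	TRBV23
B6s	TRBV	TRBV24
B6s	TRBV	TRBV26
B6s	TRBV	TRBV29
B6s	TRBV	TRBV31
B6s	TRBJ	TRBJ1-1
B6s	TRBJ	TRBJ1-2
B6s	TRBJ	TRBJ1-3
B6s	TRBJ	TRBJ1-4
B6s	TRBJ	TRBJ1-5
B6s	TRBJ	TRBJ2-1
B6s	TRBJ	TRBJ2-2
B6s	TRBJ	TRBJ2-3
B6s	TRBJ	TRBJ2-4
B6s	TRBJ	TRBJ2-5
B6s	TRBJ	TRBJ2-7
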