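>seed1 synthetic ankyrin-repeat seed instance
GDTPLHLAARNGHLEVVKLLLEHGADVNARDKD
>seed2 synthetic ankyrin-repeat seed instance
GETPLHLAAKNGHLDVVKLLLEHGADVNARDKD
>seed3 synthetic ankyrin-repeat seed instance
GDTALHIAARNGHLEVVRLLLEHGADVNARDKD
>seed4 synthetic ankyrin-repeat seed instance
GDTPLHLAVRNGHVEVVKLLIEHGADVNARDKD
>seed5 synthetic ankyrin-repeat seed instance
GDTPLHLAARNGNLEVVKLLLDHGANVNARDKD
>seed6 synthetic ankyrin-repeat seed instance
SDTPLHLAARNGHLEVVKLLLEHGADINAQDKD
>seed7 synthetic ankyrin-repeat seed instance
GDTPLHLAARSGHLEVVKALLEHGADVNARDGD
>seed8 synthetic ankyrin-repeat seed instance
GDTPLHYAARNGHLEVVKLLLEHKADVNARDKD
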