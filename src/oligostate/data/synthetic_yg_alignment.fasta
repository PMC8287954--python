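>hs first_residue=252 note=synthetic_YG_box_stand-in
EMLAEIELLQSMEISWYMSGYHTGYYMGFRQNQKEGRCSHSLN
>dm first_residue=186 note=synthetic_YG_box_stand-in
---ADIELLKAMEVSWYMSGYYTGLYMGKREN-----------
>sp first_residue=126 note=synthetic_YG_box_stand-in
----------SLEISWYMAGYYTGLAEGLA-------------
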