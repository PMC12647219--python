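# Canonical centromere proteins (CENP-F and CENP-J excluded) + NDC80 complex.
# One protein id per line; fully user-overridable via --panel FILE.
CENPA
CENPB
CENPC
CENPE
CENPH
CENPI
CENPK
CENPL
CENPM
CENPN
CENPO
CENPP
CENPQ
CENPR
CENPS
CENPT
CENPU
CENPV
CENPW
CENPX
NDC80
NUF2
SPC24
SPC25
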