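# data/

Optional external inputs.

`supplementary_s6.xls` / `.xlsx` / `.csv` — per-replicate normalized
[M+H]+ peak areas used by the published-fold-change acceptance test and by
`scripts/acceptance.py` (targets t4–t7). The file is journal supplementary
material and is not redistributable here; when absent, the corresponding
test fails with an explanatory message and the acceptance report omits
those targets.

Expected long-format columns:

| column   | content                                     |
|----------|---------------------------------------------|
| compound | metabolite name (matched case-insensitively) |
| strain   | `ATCC 21831` or `ATCC 13032`                 |
| value    | normalized [M+H]+ peak area (one replicate)  |
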