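# Plan-review center roster: which centers evaluated Case 4 on PTV-EVAL
# (PTV minus organs at risk) rather than the conventional PTV.
# ptv_eval_case4: none = conventional PTV; all = PTV-EVAL for every Case-4
# target; ptv3 = PTV-EVAL for the large target only. Test input.
center_id,ptv_eval_case4
A,none
B,none
C,none
E,none
F,none
H,none
I,all
K,all
L,ptv3
M,ptv3
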