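# Transcribed per-center organ-at-risk constraint deviations from the
# published plan review of a 10-center SABR dummy-run exercise. Same schema
# as the PTV deviation fixture. Test input, not output.
case_id,target_label,center_id,metric,grade
case1,PTV1,A,Small bowel Dmax,deviation
case1,PTV1,B,,none
case1,PTV1,C,Small bowel Dmax,minor
case1,PTV1,E,Small bowel Dmax,minor
case1,PTV1,F,,none
case1,PTV1,H,,none
case1,PTV1,I,,none
case1,PTV1,K,Duodenum Dmax,minor
case1,PTV1,K,Duodenum 10 cc,minor
case1,PTV1,L,Small bowel Dmax,major
case1,PTV1,M,,none
case2,PTV1,A,,none
case2,PTV1,B,,none
case2,PTV1,C,,none
case2,PTV1,E,,none
case2,PTV1,F,,none
case2,PTV1,H,,none
case2,PTV1,I,,none
case2,PTV1,K,,none
case2,PTV1,L,,none
case2,PTV1,M,,none
case2,PTV2,A,,none
case2,PTV2,B,,none
case2,PTV2,C,,none
case2,PTV2,E,,none
case2,PTV2,F,,none
case2,PTV2,H,,none
case2,PTV2,I,,none
case2,PTV2,K,,none
case2,PTV2,L,,none
case2,PTV2,M,,none
case2,PTV3,A,,none
case2,PTV3,B,,none
case2,PTV3,C,,none
case2,PTV3,E,,none
case2,PTV3,F,,none
case2,PTV3,H,,none
case2,PTV3,I,,none
case2,PTV3,K,,none
case2,PTV3,L,,none
case2,PTV3,M,,none
case3,PTV1,A,,none
case3,PTV1,B,,none
case3,PTV1,C,,none
case3,PTV1,E,,none
case3,PTV1,F,,none
case3,PTV1,H,,none
case3,PTV1,I,,none
case3,PTV1,K,,none
case3,PTV1,L,,none
case3,PTV1,M,,none
case4,PTV1,A,,none
case4,PTV1,B,,none
case4,PTV1,C,,none
case4,PTV1,E,,none
case4,PTV1,F,,none
case4,PTV1,H,,none
case4,PTV1,I,,none
case4,PTV1,K,,none
case4,PTV1,L,,none
case4,PTV1,M,,none
case4,PTV2,A,,none
case4,PTV2,B,,none
case4,PTV2,C,,none
case4,PTV2,E,,none
case4,PTV2,F,,none
case4,PTV2,H,,none
case4,PTV2,I,,none
case4,PTV2,K,Small bowel Dmax,major
case4,PTV2,L,,none
case4,PTV2,M,,none
case4,PTV3,A,,none
case4,PTV3,B,Small bowel 120 cc,major
case4,PTV3,C,Small bowel Dmax,major
case4,PTV3,C,Small bowel 120 cc,major
case4,PTV3,E,,none
case4,PTV3,F,Small bowel Dmax,minor
case4,PTV3,F,Small bowel 120 cc,major
case4,PTV3,H,,none
case4,PTV3,I,,none
case4,PTV3,K,Small bowel Dmax,major
case4,PTV3,K,Small bowel 120 cc,major
case4,PTV3,L,,none
case4,PTV3,M,,none
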