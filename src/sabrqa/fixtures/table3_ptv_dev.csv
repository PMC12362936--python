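# Transcribed per-center PTV dosimetry deviations from the published plan
# review of a 10-center SABR dummy-run exercise. One row per deviation plus a
# grade=none row per compliant (case, target, center) cell. grade=deviation
# means the table marked a violation without a minor/major label.
# target_multi_ptv=1 marks targets containing multiple volumes, whose
# R50%/D2cm deviations were exempted in the published review. Test input.
case_id,target_label,center_id,metric,grade,target_multi_ptv
case1,PTV1,A,,none,1
case1,PTV1,B,PTV coverage,deviation,1
case1,PTV1,C,,none,1
case1,PTV1,E,,none,1
case1,PTV1,F,,none,1
case1,PTV1,H,,none,1
case1,PTV1,I,,none,1
case1,PTV1,K,,none,1
case1,PTV1,L,PTV coverage,deviation,1
case1,PTV1,M,PTV coverage,deviation,1
case2,PTV1,A,,none,0
case2,PTV1,B,PTV coverage,deviation,0
case2,PTV1,B,R50%,deviation,0
case2,PTV1,B,D2cm,deviation,0
case2,PTV1,C,R50%,major,0
case2,PTV1,C,D2cm,major,0
case2,PTV1,E,High-dose spillage,deviation,0
case2,PTV1,E,R50%,deviation,0
case2,PTV1,E,D2cm,deviation,0
case2,PTV1,F,,none,0
case2,PTV1,H,R50%,deviation,0
case2,PTV1,H,D2cm,deviation,0
case2,PTV1,I,R50%,deviation,0
case2,PTV1,I,D2cm,deviation,0
case2,PTV1,K,R50%,deviation,0
case2,PTV1,L,PTV coverage,deviation,0
case2,PTV1,L,R50%,deviation,0
case2,PTV1,M,,none,0
case2,PTV2,A,,none,1
case2,PTV2,B,PTV coverage,deviation,1
case2,PTV2,C,,none,1
case2,PTV2,E,,none,1
case2,PTV2,F,,none,1
case2,PTV2,H,,none,1
case2,PTV2,I,,none,1
case2,PTV2,K,,none,1
case2,PTV2,L,,none,1
case2,PTV2,M,,none,1
case2,PTV3,A,,none,0
case2,PTV3,B,PTV coverage,deviation,0
case2,PTV3,B,R50%,deviation,0
case2,PTV3,C,R50%,major,0
case2,PTV3,E,R50%,deviation,0
case2,PTV3,F,,none,0
case2,PTV3,H,R50%,deviation,0
case2,PTV3,I,,none,0
case2,PTV3,K,,none,0
case2,PTV3,L,,none,0
case2,PTV3,M,,none,0
case3,PTV1,A,,none,0
case3,PTV1,B,PTV coverage,deviation,0
case3,PTV1,B,R50%,deviation,0
case3,PTV1,C,,none,0
case3,PTV1,E,R50%,deviation,0
case3,PTV1,F,,none,0
case3,PTV1,H,,none,0
case3,PTV1,I,,none,0
case3,PTV1,K,D2cm,major,0
case3,PTV1,L,,none,0
case3,PTV1,M,,none,0
case4,PTV1,A,PTV coverage,deviation,0
case4,PTV1,B,PTV coverage,deviation,0
case4,PTV1,B,R50%,deviation,0
case4,PTV1,B,D2cm,deviation,0
case4,PTV1,C,,none,0
case4,PTV1,E,,none,0
case4,PTV1,F,,none,0
case4,PTV1,H,,none,0
case4,PTV1,I,D2cm,deviation,0
case4,PTV1,K,,none,0
case4,PTV1,L,,none,0
case4,PTV1,M,,none,0
case4,PTV2,A,,none,0
case4,PTV2,B,PTV coverage,deviation,0
case4,PTV2,B,R50%,deviation,0
case4,PTV2,C,,none,0
case4,PTV2,E,,none,0
case4,PTV2,F,,none,0
case4,PTV2,H,,none,0
case4,PTV2,I,,none,0
case4,PTV2,K,,none,0
case4,PTV2,L,,none,0
case4,PTV2,M,,none,0
case4,PTV3,A,PTV coverage,deviation,0
case4,PTV3,A,R50%,deviation,0
case4,PTV3,B,PTV coverage,deviation,0
case4,PTV3,B,R50%,deviation,0
case4,PTV3,C,,none,0
case4,PTV3,E,PTV coverage,deviation,0
case4,PTV3,E,R50%,deviation,0
case4,PTV3,F,PTV coverage,major,0
case4,PTV3,H,PTV coverage,deviation,0
case4,PTV3,H,R50%,deviation,0
case4,PTV3,I,R50%,deviation,0
case4,PTV3,I,D2cm,major,0
case4,PTV3,K,PTV coverage,deviation,0
case4,PTV3,K,R50%,deviation,0
case4,PTV3,L,,none,0
case4,PTV3,M,R50%,deviation,0
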