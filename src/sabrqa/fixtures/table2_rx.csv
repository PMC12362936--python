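# Transcribed per-center dose prescriptions (total dose Gy / fraction count)
# from the published results tables of a 10-center SABR dummy-run exercise.
# shared_plan=1 marks doses prescribed in a single plan covering multiple
# target volumes. Test input, not output.
case_id,target_label,ptv_volume_cc,center_id,total_dose_gy,fractions,shared_plan
case1,PTV1,165.0,A,45,10,0
case1,PTV1,165.0,B,35,10,0
case1,PTV1,165.0,C,40,10,0
case1,PTV1,165.0,E,40,10,0
case1,PTV1,165.0,F,40,10,0
case1,PTV1,165.0,H,35,10,0
case1,PTV1,165.0,I,40,10,0
case1,PTV1,165.0,K,30,5,0
case1,PTV1,165.0,L,40,10,0
case1,PTV1,165.0,M,35,10,0
case2,PTV1,3.0,A,40,5,0
case2,PTV1,3.0,B,30,3,0
case2,PTV1,3.0,C,33,3,0
case2,PTV1,3.0,E,35,5,0
case2,PTV1,3.0,F,30,3,0
case2,PTV1,3.0,H,35,5,0
case2,PTV1,3.0,I,30,3,1
case2,PTV1,3.0,K,30,3,1
case2,PTV1,3.0,L,30,3,0
case2,PTV1,3.0,M,40,5,0
case2,PTV2,10.5,A,40,5,0
case2,PTV2,10.5,B,35,5,0
case2,PTV2,10.5,C,33,3,0
case2,PTV2,10.5,E,35,5,0
case2,PTV2,10.5,F,30,3,0
case2,PTV2,10.5,H,35,5,0
case2,PTV2,10.5,L,30,3,0
case2,PTV2,10.5,M,40,5,0
case2,PTV3,7.5,A,40,5,0
case2,PTV3,7.5,B,30,3,0
case2,PTV3,7.5,C,33,3,0
case2,PTV3,7.5,E,35,5,0
case2,PTV3,7.5,F,30,3,0
case2,PTV3,7.5,H,35,5,0
case2,PTV3,7.5,L,30,3,0
case2,PTV3,7.5,M,40,5,0
case3,PTV1,49.0,A,40,5,0
case3,PTV1,49.0,B,35,5,0
case3,PTV1,49.0,C,35,5,0
case3,PTV1,49.0,E,35,5,0
case3,PTV1,49.0,F,35,5,0
case3,PTV1,49.0,H,27,3,0
case3,PTV1,49.0,I,35,5,0
case3,PTV1,49.0,K,35,5,0
case3,PTV1,49.0,L,30,3,0
case3,PTV1,49.0,M,24,3,0
case4,PTV1,16.0,A,35,10,0
case4,PTV1,16.0,B,40,10,0
case4,PTV1,16.0,C,40,10,0
case4,PTV1,16.0,E,40,10,0
case4,PTV1,16.0,F,40,10,0
case4,PTV1,16.0,H,35,10,0
case4,PTV1,16.0,I,40,10,1
case4,PTV1,16.0,K,30,5,1
case4,PTV1,16.0,L,40,10,0
case4,PTV1,16.0,M,24,3,0
case4,PTV2,16.0,A,35,10,0
case4,PTV2,16.0,B,40,10,0
case4,PTV2,16.0,C,40,10,0
case4,PTV2,16.0,E,35,10,0
case4,PTV2,16.0,F,40,10,0
case4,PTV2,16.0,H,35,10,0
case4,PTV2,16.0,L,40,10,0
case4,PTV2,16.0,M,24,3,0
case4,PTV3,544.0,A,35,10,0
case4,PTV3,544.0,B,35,10,0
case4,PTV3,544.0,C,40,10,0
case4,PTV3,544.0,E,35,10,0
case4,PTV3,544.0,F,40,10,0
case4,PTV3,544.0,H,35,10,0
case4,PTV3,544.0,I,35,10,0
case4,PTV3,544.0,K,25,5,0
case4,PTV3,544.0,L,37,10,0
case4,PTV3,544.0,M,35,10,0
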