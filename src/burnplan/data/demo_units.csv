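unit_id,evc_code,area_ha,age
96,20,6.07,14
96,164,5.52,14
96,21,11.02,14
96,22,1.02,14
96,55,0.72,14
115,71,26.23,35
127,161,0.51,2
127,3,24.64,2
139,233,1.53,3
139,45,21.79,3
139,30,2.06,3
169,8,6.92,5
169,16,21.78,5
180,45,25.79,8
192,45,24.63,81
236,16,5.96,5
236,48,20.52,5
277,16,26.95,52
298,48,12.92,12
298,161,5.28,37
298,6,6.94,37
306,48,26.02,37
306,161,1.69,37
310,48,22.49,37
310,161,1.70,37
346,48,8.81,38
346,16,13.01,38
346,198,1.36,38
351,16,26.61,37
351,48,0.76,37
376,48,25.18,37
384,175,23.86,2
403,48,24.01,37
477,16,24.76,6
602,16,20.27,6
602,48,2.59,6
602,23,1.84,6
634,16,27.27,36
796,8,18.33,10
796,48,10.25,10
813,16,4.03,37
813,45,14.39,37
813,21,9.30,37
831,48,3.47,6
831,16,24.16,6
831,198,1.26,6
833,48,2.89,2
833,1,2.56,2
833,6,1.58,2
833,161,18.32,2
987,16,7.29,1
987,8,3.04,1
987,45,16.09,1
1033,45,25.74,81
1035,3,2.03,37
1035,161,17.48,37
1035,163,5.62,37
1049,16,7.97,16
1049,48,18.69,37
1081,48,14.97,25
1081,16,6.82,25
1081,178,2.22,55
1093,48,13.15,37
1093,161,12.81,37
1093,163,1.15,37
1107,22,23.59,2
1107,47,1.48,2
1121,20,26.43,6
1125,20,14.15,5
1125,22,13.20,5
1130,20,27.54,14
1134,16,13.79,3
1134,20,1.60,3
1134,22,7.72,3
1151,20,25.69,15
1152,20,18.74,4
1152,47,8.33,4
1171,851,3.39,3
1171,20,4.91,3
1171,22,19.55,3
1179,20,25.65,27
1181,16,19.08,8
1181,20,7.29,8
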