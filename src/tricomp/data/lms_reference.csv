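measure,sex,age_years,L,M,S
bmi,female,10.0,-1.5,16.6,0.125
bmi,female,10.5,-1.49,17.072,0.1255
bmi,female,11.0,-1.48,17.538,0.126
bmi,female,11.5,-1.47,17.998,0.1265
bmi,female,12.0,-1.46,18.452,0.127
bmi,female,12.5,-1.45,18.9,0.1275
bmi,female,13.0,-1.44,19.342,0.128
bmi,female,13.5,-1.43,19.778,0.1285
bmi,female,14.0,-1.42,20.208,0.129
bmi,female,14.5,-1.41,20.632,0.1295
bmi,female,15.0,-1.4,21.05,0.13
bmi,female,15.5,-1.39,21.462,0.1305
bmi,female,16.0,-1.38,21.868,0.131
bmi,female,16.5,-1.37,22.268,0.1315
bmi,female,17.0,-1.36,22.662,0.132
bmi,female,17.5,-1.35,23.05,0.1325
bmi,female,18.0,-1.34,23.432,0.133
bmi,female,18.5,-1.33,23.808,0.1335
bmi,female,19.0,-1.32,24.178,0.134
bmi,female,19.5,-1.31,24.542,0.1345
bmi,female,20.0,-1.3,24.9,0.135
bmi,female,20.5,-1.29,25.252,0.1355
bmi,female,21.0,-1.28,25.598,0.136
bmi,female,21.5,-1.27,25.938,0.1365
bmi,female,22.0,-1.26,26.272,0.137
bmi,female,22.5,-1.25,26.6,0.1375
bmi,female,23.0,-1.24,26.922,0.138
bmi,female,23.5,-1.23,27.238,0.1385
bmi,female,24.0,-1.22,27.548,0.139
bmi,female,24.5,-1.21,27.852,0.1395
bmi,female,25.0,-1.2,28.15,0.14
bmi,male,10.0,-1.5,16.4,0.125
bmi,male,10.5,-1.49,16.872,0.1255
bmi,male,11.0,-1.48,17.338,0.126
bmi,male,11.5,-1.47,17.798,0.1265
bmi,male,12.0,-1.46,18.252,0.127
bmi,male,12.5,-1.45,18.7,0.1275
bmi,male,13.0,-1.44,19.142,0.128
bmi,male,13.5,-1.43,19.578,0.1285
bmi,male,14.0,-1.42,20.008,0.129
bmi,male,14.5,-1.41,20.432,0.1295
bmi,male,15.0,-1.4,20.85,0.13
bmi,male,15.5,-1.39,21.262,0.1305
bmi,male,16.0,-1.38,21.668,0.131
bmi,male,16.5,-1.37,22.068,0.1315
bmi,male,17.0,-1.36,22.462,0.132
bmi,male,17.5,-1.35,22.85,0.1325
bmi,male,18.0,-1.34,23.232,0.133
bmi,male,18.5,-1.33,23.608,0.1335
bmi,male,19.0,-1.32,23.978,0.134
bmi,male,19.5,-1.31,24.342,0.1345
bmi,male,20.0,-1.3,24.7,0.135
bmi,male,20.5,-1.29,25.052,0.1355
bmi,male,21.0,-1.28,25.398,0.136
bmi,male,21.5,-1.27,25.738,0.1365
bmi,male,22.0,-1.26,26.072,0.137
bmi,male,22.5,-1.25,26.4,0.1375
bmi,male,23.0,-1.24,26.722,0.138
bmi,male,23.5,-1.23,27.038,0.1385
bmi,male,24.0,-1.22,27.348,0.139
bmi,male,24.5,-1.21,27.652,0.1395
bmi,male,25.0,-1.2,27.95,0.14
waist,female,10.0,-0.9,62.0,0.1
waist,female,10.5,-0.9,62.7,0.1004
waist,female,11.0,-0.9,63.4,0.1008
waist,female,11.5,-0.9,64.1,0.1012
waist,female,12.0,-0.9,64.8,0.1016
waist,female,12.5,-0.9,65.5,0.102
waist,female,13.0,-0.9,66.2,0.1024
waist,female,13.5,-0.9,66.9,0.1028
waist,female,14.0,-0.9,67.6,0.1032
waist,female,14.5,-0.9,68.3,0.1036
waist,female,15.0,-0.9,69.0,0.104
waist,female,15.5,-0.9,69.7,0.1044
waist,female,16.0,-0.9,70.4,0.1048
waist,female,16.5,-0.9,71.1,0.1052
waist,female,17.0,-0.9,71.8,0.1056
waist,female,17.5,-0.9,72.5,0.106
waist,female,18.0,-0.9,73.2,0.1064
waist,female,18.5,-0.9,73.9,0.1068
waist,female,19.0,-0.9,74.6,0.1072
waist,female,19.5,-0.9,75.3,0.1076
waist,female,20.0,-0.9,76.0,0.108
waist,female,20.5,-0.9,76.7,0.1084
waist,female,21.0,-0.9,77.4,0.1088
waist,female,21.5,-0.9,78.1,0.1092
waist,female,22.0,-0.9,78.8,0.1096
waist,female,22.5,-0.9,79.5,0.11
waist,female,23.0,-0.9,80.2,0.1104
waist,female,23.5,-0.9,80.9,0.1108
waist,female,24.0,-0.9,81.6,0.1112
waist,female,24.5,-0.9,82.3,0.1116
waist,female,25.0,-0.9,83.0,0.112
waist,male,10.0,-0.9,63.5,0.1
waist,male,10.5,-0.9,64.2,0.1004
waist,male,11.0,-0.9,64.9,0.1008
waist,male,11.5,-0.9,65.6,0.1012
waist,male,12.0,-0.9,66.3,0.1016
waist,male,12.5,-0.9,67.0,0.102
waist,male,13.0,-0.9,67.7,0.1024
waist,male,13.5,-0.9,68.4,0.1028
waist,male,14.0,-0.9,69.1,0.1032
waist,male,14.5,-0.9,69.8,0.1036
waist,male,15.0,-0.9,70.5,0.104
waist,male,15.5,-0.9,71.2,0.1044
waist,male,16.0,-0.9,71.9,0.1048
waist,male,16.5,-0.9,72.6,0.1052
waist,male,17.0,-0.9,73.3,0.1056
waist,male,17.5,-0.9,74.0,0.106
waist,male,18.0,-0.9,74.7,0.1064
waist,male,18.5,-0.9,75.4,0.1068
waist,male,19.0,-0.9,76.1,0.1072
waist,male,19.5,-0.9,76.8,0.1076
waist,male,20.0,-0.9,77.5,0.108
waist,male,20.5,-0.9,78.2,0.1084
waist,male,21.0,-0.9,78.9,0.1088
waist,male,21.5,-0.9,79.6,0.1092
waist,male,22.0,-0.9,80.3,0.1096
waist,male,22.5,-0.9,81.0,0.11
waist,male,23.0,-0.9,81.7,0.1104
waist,male,23.5,-0.9,82.4,0.1108
waist,male,24.0,-0.9,83.1,0.1112
waist,male,24.5,-0.9,83.8,0.1116
waist,male,25.0,-0.9,84.5,0.112
waist_height,female,10.0,-1.2,0.452,0.075
waist_height,female,10.5,-1.2,0.4512,0.075
waist_height,female,11.0,-1.2,0.4505,0.075
waist_height,female,11.5,-1.2,0.4498,0.075
waist_height,female,12.0,-1.2,0.449,0.075
waist_height,female,12.5,-1.2,0.4482,0.075
waist_height,female,13.0,-1.2,0.4475,0.075
waist_height,female,13.5,-1.2,0.4468,0.075
waist_height,female,14.0,-1.2,0.446,0.075
waist_height,female,14.5,-1.2,0.4452,0.075
waist_height,female,15.0,-1.2,0.4445,0.075
waist_height,female,15.5,-1.2,0.4438,0.075
waist_height,female,16.0,-1.2,0.443,0.075
waist_height,female,16.5,-1.2,0.4422,0.075
waist_height,female,17.0,-1.2,0.4415,0.075
waist_height,female,17.5,-1.2,0.4408,0.075
waist_height,female,18.0,-1.2,0.44,0.075
waist_height,female,18.5,-1.2,0.4392,0.075
waist_height,female,19.0,-1.2,0.4385,0.075
waist_height,female,19.5,-1.2,0.4378,0.075
waist_height,female,20.0,-1.2,0.437,0.075
waist_height,female,20.5,-1.2,0.4362,0.075
waist_height,female,21.0,-1.2,0.4355,0.075
waist_height,female,21.5,-1.2,0.4348,0.075
waist_height,female,22.0,-1.2,0.434,0.075
waist_height,female,22.5,-1.2,0.4332,0.075
waist_height,female,23.0,-1.2,0.4325,0.075
waist_height,female,23.5,-1.2,0.4318,0.075
waist_height,female,24.0,-1.2,0.431,0.075
waist_height,female,24.5,-1.2,0.4302,0.075
waist_height,female,25.0,-1.2,0.4295,0.075
waist_height,male,10.0,-1.2,0.457,0.075
waist_height,male,10.5,-1.2,0.4562,0.075
waist_height,male,11.0,-1.2,0.4555,0.075
waist_height,male,11.5,-1.2,0.4548,0.075
waist_height,male,12.0,-1.2,0.454,0.075
waist_height,male,12.5,-1.2,0.4532,0.075
waist_height,male,13.0,-1.2,0.4525,0.075
waist_height,male,13.5,-1.2,0.4518,0.075
waist_height,male,14.0,-1.2,0.451,0.075
waist_height,male,14.5,-1.2,0.4502,0.075
waist_height,male,15.0,-1.2,0.4495,0.075
waist_height,male,15.5,-1.2,0.4488,0.075
waist_height,male,16.0,-1.2,0.448,0.075
waist_height,male,16.5,-1.2,0.4472,0.075
waist_height,male,17.0,-1.2,0.4465,0.075
waist_height,male,17.5,-1.2,0.4458,0.075
waist_height,male,18.0,-1.2,0.445,0.075
waist_height,male,18.5,-1.2,0.4442,0.075
waist_height,male,19.0,-1.2,0.4435,0.075
waist_height,male,19.5,-1.2,0.4428,0.075
waist_height,male,20.0,-1.2,0.442,0.075
waist_height,male,20.5,-1.2,0.4412,0.075
waist_height,male,21.0,-1.2,0.4405,0.075
waist_height,male,21.5,-1.2,0.4398,0.075
waist_height,male,22.0,-1.2,0.439,0.075
waist_height,male,22.5,-1.2,0.4382,0.075
waist_height,male,23.0,-1.2,0.4375,0.075
waist_height,male,23.5,-1.2,0.4368,0.075
waist_height,male,24.0,-1.2,0.436,0.075
waist_height,male,24.5,-1.2,0.4352,0.075
waist_height,male,25.0,-1.2,0.4345,0.075
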