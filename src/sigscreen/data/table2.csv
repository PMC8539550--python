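solvent,scale,x2_star,T,x_printed,x_sd_printed
"1,4-dioxane",1e-4,0.0,298.15,0.34,0.01
"1,4-dioxane",1e-4,0.0,303.15,0.41,0.02
"1,4-dioxane",1e-4,0.0,308.15,0.48,0.01
"1,4-dioxane",1e-4,0.0,313.15,0.58,0.02
"1,4-dioxane",1e-4,0.2,298.15,36.00,1.06
"1,4-dioxane",1e-4,0.2,303.15,40.20,1.61
"1,4-dioxane",1e-4,0.2,308.15,43.88,2.51
"1,4-dioxane",1e-4,0.2,313.15,49.37,2.90
"1,4-dioxane",1e-4,0.4,298.15,69.74,2.14
"1,4-dioxane",1e-4,0.4,303.15,79.01,2.74
"1,4-dioxane",1e-4,0.4,308.15,89.97,2.50
"1,4-dioxane",1e-4,0.4,313.15,103.25,2.35
"1,4-dioxane",1e-4,0.6,298.15,74.69,3.14
"1,4-dioxane",1e-4,0.6,303.15,86.23,2.56
"1,4-dioxane",1e-4,0.6,308.15,99.46,3.01
"1,4-dioxane",1e-4,0.6,313.15,115.37,3.04
"1,4-dioxane",1e-4,0.8,298.15,47.15,1.50
"1,4-dioxane",1e-4,0.8,303.15,52.31,1.66
"1,4-dioxane",1e-4,0.8,308.15,57.73,2.33
"1,4-dioxane",1e-4,0.8,313.15,64.57,2.94
"1,4-dioxane",1e-4,1.0,298.15,10.03,0.32
"1,4-dioxane",1e-4,1.0,303.15,10.79,0.39
"1,4-dioxane",1e-4,1.0,308.15,11.63,0.64
"1,4-dioxane",1e-4,1.0,313.15,12.49,0.57
methanol,1e-4,0.2,298.15,2.12,0.13
methanol,1e-4,0.2,303.15,2.57,0.14
methanol,1e-4,0.2,308.15,3.06,0.12
methanol,1e-4,0.2,313.15,3.69,0.23
methanol,1e-4,0.4,298.15,8.58,0.43
methanol,1e-4,0.4,303.15,9.50,0.38
methanol,1e-4,0.4,308.15,10.36,0.48
methanol,1e-4,0.4,313.15,11.50,0.58
methanol,1e-4,0.6,298.15,21.88,0.68
methanol,1e-4,0.6,303.15,23.29,0.68
methanol,1e-4,0.6,308.15,24.86,0.56
methanol,1e-4,0.6,313.15,26.53,0.57
methanol,1e-4,0.8,298.15,33.36,0.68
methanol,1e-4,0.8,303.15,35.54,0.82
methanol,1e-4,0.8,308.15,37.89,0.78
methanol,1e-4,0.8,313.15,40.62,1.12
methanol,1e-4,1.0,298.15,38.72,0.91
methanol,1e-4,1.0,303.15,41.10,1.35
methanol,1e-4,1.0,308.15,43.68,1.30
methanol,1e-4,1.0,313.15,46.70,1.20
DMF,1e-2,0.2,298.15,3.99,0.21
DMF,1e-2,0.2,303.15,4.99,0.26
DMF,1e-2,0.2,308.15,6.19,0.21
DMF,1e-2,0.2,313.15,7.68,0.17
DMF,1e-2,0.4,298.15,8.04,0.57
DMF,1e-2,0.4,303.15,11.13,0.36
DMF,1e-2,0.4,308.15,14.31,0.19
DMF,1e-2,0.4,313.15,18.16,0.98
DMF,1e-2,0.6,298.15,12.37,0.78
DMF,1e-2,0.6,303.15,17.57,0.68
DMF,1e-2,0.6,308.15,22.71,0.99
DMF,1e-2,0.6,313.15,28.58,0.61
DMF,1e-2,0.8,298.15,17.22,0.82
DMF,1e-2,0.8,303.15,23.45,0.64
DMF,1e-2,0.8,308.15,30.53,0.98
DMF,1e-2,0.8,313.15,37.94,0.48
DMF,1e-2,1.0,298.15,22.69,0.87
DMF,1e-2,1.0,303.15,29.91,1.02
DMF,1e-2,1.0,308.15,38.05,0.86
DMF,1e-2,1.0,313.15,46.50,1.16
DMSO,1e-2,0.2,298.15,0.45,0.02
DMSO,1e-2,0.2,303.15,0.81,0.04
DMSO,1e-2,0.2,308.15,1.31,0.04
DMSO,1e-2,0.2,313.15,1.89,0.02
DMSO,1e-2,0.4,298.15,1.08,0.05
DMSO,1e-2,0.4,303.15,2.41,0.14
DMSO,1e-2,0.4,308.15,3.69,0.15
DMSO,1e-2,0.4,313.15,5.22,0.20
DMSO,1e-2,0.6,298.15,3.40,0.16
DMSO,1e-2,0.6,303.15,4.98,0.03
DMSO,1e-2,0.6,308.15,6.89,0.25
DMSO,1e-2,0.6,313.15,9.32,0.23
DMSO,1e-2,0.8,298.15,7.89,0.34
DMSO,1e-2,0.8,303.15,10.16,0.55
DMSO,1e-2,0.8,308.15,12.98,0.69
DMSO,1e-2,0.8,313.15,16.54,0.57
DMSO,1e-2,1.0,298.15,17.97,0.66
DMSO,1e-2,1.0,303.15,21.05,0.57
DMSO,1e-2,1.0,308.15,24.81,0.10
DMSO,1e-2,1.0,313.15,29.30,0.60
acetonitrile,1e-3,0.2,298.15,3.24,0.18
acetonitrile,1e-3,0.2,303.15,3.62,0.10
acetonitrile,1e-3,0.2,308.15,4.03,0.14
acetonitrile,1e-3,0.2,313.15,4.54,0.17
acetonitrile,1e-3,0.4,298.15,9.02,0.39
acetonitrile,1e-3,0.4,303.15,10.05,0.23
acetonitrile,1e-3,0.4,308.15,11.22,0.29
acetonitrile,1e-3,0.4,313.15,12.51,0.38
acetonitrile,1e-3,0.6,298.15,12.04,0.24
acetonitrile,1e-3,0.6,303.15,13.29,0.36
acetonitrile,1e-3,0.6,308.15,14.62,0.39
acetonitrile,1e-3,0.6,313.15,16.16,0.18
acetonitrile,1e-3,0.8,298.15,6.92,0.26
acetonitrile,1e-3,0.8,303.15,7.89,0.37
acetonitrile,1e-3,0.8,308.15,8.91,0.41
acetonitrile,1e-3,0.8,313.15,10.05,0.43
acetonitrile,1e-3,1.0,298.15,2.83,0.08
acetonitrile,1e-3,1.0,303.15,3.04,0.07
acetonitrile,1e-3,1.0,308.15,3.21,0.09
acetonitrile,1e-3,1.0,313.15,3.43,0.08
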