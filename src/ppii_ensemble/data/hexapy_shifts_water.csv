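residue_index,residue,atom,shift_ppm,condition,temperature_K
1,PRO,HA,4.18,water,300
1,PRO,HB2,2.10,water,300
1,PRO,HB3,1.67,water,300
1,PRO,HG,1.81,water,300
1,PRO,HD,3.48,water,300
2,HIS,H,8.47,water,300
2,HIS,HA,4.57,water,300
2,HIS,HB2,3.11,water,300
2,HIS,HB3,3.02,water,300
2,HIS,HD2,7.12,water,300
2,HIS,HE1,8.46,water,300
3,ASN,H,8.34,water,300
3,ASN,HA,4.83,water,300
3,ASN,HB2,2.69,water,300
3,ASN,HB3,2.56,water,300
3,ASN,HD21,7.47,water,300
3,ASN,HD22,6.81,water,300
4,PRO,HA,4.29,water,300
4,PRO,HB2,2.13,water,300
4,PRO,HB3,1.80,water,300
4,PRO,HG,1.88,water,300
4,PRO,HD2,3.64,water,300
4,PRO,HD3,3.60,water,300
5,GLY,H,8.21,water,300
5,GLY,HA,3.73,water,300
6,TYR,H,7.81,water,300
6,TYR,HA,4.69,water,300
6,TYR,HB2,2.94,water,300
6,TYR,HB3,2.78,water,300
6,TYR,HD,6.93,water,300
6,TYR,HE,6.69,water,300
7,PRO,HA,4.24,water,300
7,PRO,HB2,2.09,water,300
7,PRO,HB3,1.68,water,300
7,PRO,HG,1.81,water,300
7,PRO,HD2,3.62,water,300
7,PRO,HD3,3.32,water,300
8,HIS,H,8.36,water,300
8,HIS,HA,4.55,water,300
8,HIS,HB2,3.11,water,300
8,HIS,HB3,3.03,water,300
8,HIS,HD2,7.15,water,300
8,HIS,HE1,8.47,water,300
9,ASN,H,8.38,water,300
9,ASN,HA,4.83,water,300
9,ASN,HB2,2.68,water,300
9,ASN,HB3,2.54,water,300
9,ASN,HD21,7.49,water,300
9,ASN,HD22,6.82,water,300
10,PRO,HA,4.31,water,300
10,PRO,HB2,2.13,water,300
10,PRO,HB3,1.79,water,300
10,PRO,HG,1.88,water,300
10,PRO,HD2,3.65,water,300
10,PRO,HD3,3.61,water,300
11,GLY,H,8.28,water,300
11,GLY,HA2,3.78,water,300
11,GLY,HA3,3.72,water,300
12,TYR,H,7.79,water,300
12,TYR,HA,4.39,water,300
12,TYR,HB2,2.96,water,300
12,TYR,HB3,2.85,water,300
12,TYR,HD,7.00,water,300
12,TYR,HE,6.70,water,300
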