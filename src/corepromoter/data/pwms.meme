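MEME version 4

ALPHABET= ACGT

strands: +

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF Inr_dros
letter-probability matrix: alength= 4 w= 6 nsites= 10000 E= 0
 0.019231 0.019231 0.019231 0.942308
 0.005508 0.979192 0.005508 0.009792
 0.989726 0.003425 0.003425 0.003425
 0.064286 0.007143 0.578571 0.350000
 0.015267 0.003817 0.003817 0.977099
 0.006098 0.493902 0.006098 0.493902

MOTIF Inr_mamm
letter-probability matrix: alength= 4 w= 7 nsites= 10000 E= 0
 0.020000 0.480000 0.020000 0.480000
 0.020000 0.480000 0.020000 0.480000
 0.940000 0.020000 0.020000 0.020000
 0.250000 0.250000 0.250000 0.250000
 0.480000 0.020000 0.020000 0.480000
 0.240000 0.330000 0.100000 0.330000
 0.140000 0.330000 0.200000 0.330000

MOTIF TATA
letter-probability matrix: alength= 4 w= 8 nsites= 10000 E= 0
 0.009792 0.005508 0.005508 0.979192
 0.989726 0.003425 0.003425 0.003425
 0.003425 0.003425 0.003425 0.989726
 0.989726 0.003425 0.003425 0.003425
 0.493902 0.006098 0.006098 0.493902
 0.953390 0.004237 0.004237 0.038136
 0.493902 0.006098 0.006098 0.493902
 0.470588 0.029412 0.470588 0.029412

MOTIF BridgeI
letter-probability matrix: alength= 4 w= 5 nsites= 10000 E= 0
 0.171875 0.640625 0.015625 0.171875
 0.015625 0.015625 0.953125 0.015625
 0.328125 0.484375 0.171875 0.015625
 0.328125 0.015625 0.171875 0.484375
 0.015625 0.171875 0.484375 0.328125

MOTIF BridgeII
letter-probability matrix: alength= 4 w= 4 nsites= 10000 E= 0
 0.713437 0.017163 0.017163 0.252238
 0.158569 0.626799 0.056063 0.158569
 0.056063 0.158569 0.626799 0.158569
 0.017163 0.017163 0.252238 0.713437

MOTIF DPE
letter-probability matrix: alength= 4 w= 6 nsites= 10000 E= 0
 0.581937 0.003724 0.410615 0.003724
 0.005495 0.197802 0.791209 0.005495
 0.539326 0.003745 0.003745 0.453184
 0.123077 0.492308 0.007692 0.376923
 0.049156 0.181792 0.727167 0.041885
 0.005495 0.005495 0.197802 0.791209

MOTIF MTE
letter-probability matrix: alength= 4 w= 12 nsites= 10000 E= 0
 0.060811 0.817568 0.060811 0.060811
 0.029412 0.470588 0.470588 0.029412
 0.942308 0.019231 0.019231 0.019231
 0.470588 0.029412 0.470588 0.029412
 0.060811 0.817568 0.060811 0.060811
 0.029412 0.470588 0.470588 0.029412
 0.029412 0.470588 0.470588 0.029412
 0.942308 0.019231 0.019231 0.019231
 0.942308 0.019231 0.019231 0.019231
 0.060811 0.817568 0.060811 0.060811
 0.060811 0.060811 0.817568 0.060811
 0.029412 0.470588 0.470588 0.029412
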