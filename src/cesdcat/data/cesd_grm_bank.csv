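item_id,a,b1,b2,b3,se_a,se_b1,se_b2,se_b3
q1,1.22,-0.97,0.93,2.85,0.09,0.09,0.09,0.15
q3,3.15,-1.56,1.14,3.50,0.18,0.15,0.15,0.21
q4,1.45,-1.31,0.20,2.16,0.09,0.10,0.09,0.12
q5,1.14,-2.13,-0.38,1.44,0.08,0.15,0.08,0.10
q6,3.70,-2.81,0.37,3.70,0.22,0.21,0.16,0.24
q7,1.13,-1.71,0.04,1.81,0.07,0.10,0.08,0.10
q8,1.37,-1.84,0.19,2.11,0.09,0.11,0.09,0.12
q9,2.03,-0.81,0.86,2.66,0.12,0.11,0.11,0.15
q10,1.29,-0.66,0.79,2.56,0.09,0.09,0.09,0.13
q12,2.14,-2.09,0.65,3.33,0.13,0.15,0.12,0.18
q13,1.49,-1.27,0.58,2.49,0.09,0.10,0.09,0.13
q14,1.98,-2.59,-0.70,1.25,0.11,0.14,0.11,0.11
q16,2.12,-2.06,0.44,2.98,0.13,0.14,0.12,0.16
q17,1.38,0.15,1.57,3.24,0.10,0.09,0.11,0.18
q18,2.89,-3.31,-0.34,2.82,0.16,0.20,0.14,0.18
q19,1.50,-1.21,0.41,2.15,0.10,0.10,0.09,0.12
q20,1.37,-1.99,0.09,1.83,0.09,0.12,0.09,0.11
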