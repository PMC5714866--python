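subset,mtry,sensitivity,specificity,precision,accuracy,mcc
Train0.5per,3,0.9296,0.8867,0.9525,0.9171,0.803
Train0.5per,5,0.9359,0.884,0.9503,0.9205,0.8117
Train0.5per,7,0.9376,0.873,0.9446,0.918,0.8067
Train0.5per,9,0.9428,0.8694,0.9419,0.9202,0.8126
Train0.5per,11,0.9423,0.8667,0.9406,0.919,0.8099
Train0.5per,14,0.9422,0.8659,0.9402,0.9186,0.8092
Train1per,10,0.9454,0.8754,0.9446,0.9238,0.8212
Train1per,15,0.9457,0.8712,0.9424,0.9226,0.8187
Train1per,20,0.949,0.8713,0.9419,0.9247,0.8242
Train1per,25,0.9476,0.8667,0.9397,0.9223,0.8186
Train1per,30,0.9472,0.8658,0.9393,0.9217,0.8171
Train1per,35,0.9469,0.8699,0.9415,0.9229,0.8197
Train1per,40,0.9472,0.8649,0.9388,0.9214,0.8165
Train5per,11,0.9504,0.8751,0.9437,0.9267,0.8291
Train5per,17,0.9486,0.8721,0.9424,0.9247,0.824
Train5per,22,0.9496,0.8783,0.9454,0.9275,0.8302
Train5per,27,0.9493,0.8817,0.9472,0.9284,0.8321
Train5per,32,0.9484,0.8797,0.9463,0.9272,0.8292
Train5per,37,0.9494,0.8843,0.9485,0.9293,0.8341
Train5per,44,0.9519,0.8841,0.9481,0.9308,0.838
Train10per,32,0.9508,0.877,0.9446,0.9278,0.8312
Train10per,44,0.9514,0.8831,0.9476,0.9302,0.8366
Train10per,64,0.9511,0.8856,0.949,0.9308,0.8378
Train10per,88,0.9524,0.8877,0.9498,0.9324,0.8414
Train10per,108,0.9515,0.8866,0.9494,0.9314,0.8392
Train10per,128,0.9515,0.8857,0.949,0.9311,0.8386
Train20per,44,0.9518,0.8806,0.9463,0.9296,0.8353
Train20per,66,0.9506,0.882,0.9472,0.9293,0.8344
Train20per,88,0.9502,0.8828,0.9476,0.9293,0.8343
Train20per,128,0.9506,0.8855,0.949,0.9305,0.837
Train20per,176,0.9507,0.8864,0.9494,0.9308,0.8377
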