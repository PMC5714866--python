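subset,mtry,sensitivity,specificity,precision,accuracy,mcc
Top20,6,0.9429,0.8802,0.9479,0.9240,0.8203
Top20,8,0.9434,0.8812,0.9484,0.9246,0.8218
Top20,10,0.9421,0.8782,0.9470,0.9228,0.8174
Top20,12,0.9418,0.8927,0.9542,0.9272,0.8272
Top20,14,0.9436,0.8734,0.9444,0.9222,0.8165
Top40,4,0.9421,0.8791,0.9475,0.9231,0.8181
Top40,5,0.9434,0.8830,0.9492,0.9252,0.8231
Top40,6,0.9431,0.8847,0.9501,0.9255,0.8237
Top40,7,0.9454,0.8800,0.9475,0.9255,0.8243
Top40,8,0.9433,0.8794,0.9475,0.9240,0.8204
Top60,16,0.9477,0.8905,0.9523,0.9304,0.8356
Top60,24,0.9468,0.8848,0.9497,0.9280,0.8300
Top60,32,0.9480,0.8861,0.9501,0.9292,0.8330
Top60,40,0.9477,0.8878,0.9510,0.9295,0.8335
Top60,48,0.9472,0.8850,0.9497,0.9283,0.8307
Top80,12,0.9468,0.8857,0.9501,0.9283,0.8306
Top80,18,0.9448,0.8879,0.9515,0.9277,0.8289
Top80,24,0.9455,0.8836,0.9492,0.9268,0.8270
Top80,30,0.9476,0.8851,0.9497,0.9286,0.8315
Top80,36,0.9439,0.8849,0.9501,0.9261,0.8253
Top100,3,0.9473,0.8904,0.9523,0.9301,0.8348
Top100,5,0.9470,0.8948,0.9545,0.9314,0.8375
Top100,7,0.9469,0.8884,0.9515,0.9292,0.8327
Top100,9,0.9474,0.8922,0.9532,0.9307,0.8362
Top100,11,0.9473,0.8904,0.9523,0.9301,0.8348
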