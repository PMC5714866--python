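name,observed,predicted
Glipizide,-4.58,-4.54
Ceftriaxone,-4.46,-4.77
Dextromethorphan,-4.74,-4.40
Olopatadine,-4.72,-5.09
Sulfasalazine,-4.49,-4.46
Diazepam,-4.74,-4.70
Oxazepam,-4.95,-4.60
Diflunisal,-5.48,-5.58
Thalidomide,-4.70,-4.55
Verapamil,-4.31,-4.46
Daidzein,-6.60,-5.78
Vinblastine,-3.92,-4.34
Griseofulvin,-4.68,-4.73
Diclofenac,-5.01,-4.64
Cytarabine,-4.63,-4.18
Methanol,-3.93,-4.76
choline,-5.38,-5.06
progesterone,-6.10,-5.60
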