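[meta]
k = 2.5

["REF-F"]
family = "double_logistic"
A1 = 1723.4685955943612
r1 = 0.45
c1 = 1.5
A2 = 1723.4685955943612
r2 = 0.6700763685989582
c2 = 6.4376078624240565
alpha = 0.009573716656153955

["REF-M"]
family = "double_logistic"
A1 = 1784.6138057145236
r1 = 0.45
c1 = 1.5
A2 = 2181.194651428862
r2 = 0.9
c2 = 8.079067244959326
alpha = 0.009834060424615695

["REF-T-F"]
family = "logistic_with_decline"
base = 0.0
amp = 1.6
r = 1.8
c = 4.0
decline = 0.004
t_dec = 30.0

["REF-T-M"]
family = "logistic_with_decline"
base = 0.0
amp = 2.4
r = 1.8
c = 7.0
decline = 0.004
t_dec = 30.0

["REF-DHEA"]
family = "saturating_exp"
base = 1.0
amp = 2.0
tau = 3.29197093350053

["REF-IGFBP3"]
family = "gaussian_bump"
base = 2.0
amp = 1.0
mu = 6.0
width = 3.0
mu_male = 9.5
width_male = 3.5
amp_male = 1.0
base_male = 2.0

["REF-CREA-F"]
family = "saturating_exp"
base = -0.5
amp = 1.2
tau = 2.5

["REF-CREA-M"]
family = "offset_double_logistic"
A1 = 0.9
r1 = 0.45
c1 = 1.5
A2 = 0.7
r2 = 0.9
c2 = 9.570128536053417
base = -0.5

[noise]
sigma_weight = 0.04
sigma_length = 0.02
sigma_hormone = 0.3
sd_size = 0.08
sd_timing = 0.5
sd_zoo = 0.05
creatinine_young_factor = 1.5
pregnant_prob = 0.1
pregnant_factor = 1.1
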