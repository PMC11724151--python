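carry,266667
growrate,1.15
bevmort,0.44
max_dispersal_dist,1
mean_dispersal_dist,0.0005
mass,23.82
lower_limit_temperature,-3.36
optimum_temperature,10.2
upper_limit_temperature,15.28
lower_limit_precipitation,297
optimum_precipitation,1000
upper_limit_precipitation,2772
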