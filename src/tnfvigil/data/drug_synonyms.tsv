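term	canonical
adalimumab	adalimumab
humira	adalimumab
trudexa	adalimumab
amjevita	adalimumab
cyltezo	adalimumab
hyrimoz	adalimumab
imraldi	adalimumab
hadlima	adalimumab
idacio	adalimumab
yuflyma	adalimumab
abrilada	adalimumab
adalimumab-atto	adalimumab
adalimumab-adbm	adalimumab
golimumab	golimumab
simponi	golimumab
simponi aria	golimumab
certolizumab	certolizumab
certolizumab pegol	certolizumab
cimzia	certolizumab
etanercept	etanercept
enbrel	etanercept
benepali	etanercept
erelzi	etanercept
eticovo	etanercept
etanercept-szzs	etanercept
infliximab	infliximab
remicade	infliximab
remsima	infliximab
inflectra	infliximab
renflexis	infliximab
avsola	infliximab
ixifi	infliximab
infliximab-dyyb	infliximab
infliximab-abda	infliximab
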