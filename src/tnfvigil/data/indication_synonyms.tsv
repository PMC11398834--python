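term	canonical
rheumatoid arthritis	rheumatoid arthritis
ra	rheumatoid arthritis
rheumatoid arthritis (ra)	rheumatoid arthritis
seropositive rheumatoid arthritis	rheumatoid arthritis
arthritis rheumatoid	rheumatoid arthritis
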