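{
 "cavity_profiles.tsv": "d1af6933870d19a7114538444753de2a519d412d03aa22040c7c48e77a6af520",
 "dimer_profiles.tsv": "2859356ccb98e3a906ab8ee98f09f72d37e6b889e80e7d68aaecfc6c8ac25a0a"
}
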