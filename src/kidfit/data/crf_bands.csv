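sex,band,upper
female,very poor,24.9
female,poor,30.9
female,fair,34.9
female,good,38.9
female,excellent,41.9
female,superior,inf
male,very poor,34.9
male,poor,38.3
male,fair,45.1
male,good,50.9
male,excellent,55.9
male,superior,inf
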