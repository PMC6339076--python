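>s1 worked-example first sequence
AEBACFDADB
>s2 worked-example second sequence
CABDACDADB
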