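timestamp,temperature,humidity,soil_moisture
16 April 2011 2:00,37,85,782
16 April 2011 2:15,35,92,780
16 April 2011 2:30,36,87,776
16 April 2011 2:45,38,84,775
16 April 2011 3:00,35,91,774
16 April 2011 3:15,37,85,772
16 April 2011 3:30,38,83,770
16 April 2011 3:45,35,90,767
17 April 2011 0:00,38,81,762
17 April 2011 0:15,36,86,756
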