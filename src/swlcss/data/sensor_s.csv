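timestamp,temperature,humidity,soil_moisture
15 April 2011 22:00,35,92,780
15 April 2011 22:15,39,82,778
15 April 2011 22:30,36,87,776
15 April 2011 22:45,35,91,774
15 April 2011 23:00,37,85,772
15 April 2011 23:15,36,87,772
15 April 2011 23:30,38,83,770
15 April 2011 23:45,35,90,767
15 April 2011 00:00,38,82,762
15 April 2011 00:15,36,86,756
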