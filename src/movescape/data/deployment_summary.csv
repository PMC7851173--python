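animal_id,tag_date,n_locations,tracking_days
1,2004-02-13,128,75
2,2004-02-19,119,62.7
3,2004-02-12,110,36
4,2004-02-18,140,47.6
5,2013-04-01,304,45.1
6,2013-04-23,68,8.1
7,2015-04-17,314,48.7
8,2015-04-13,130,21.6
9,2015-04-09,49,17.1
10,2016-04-04,129,20.1
11,2016-04-05,1710,105.2
12,2019-02-03,649,100
13,2019-02-06,1122,71.4
14,2019-04-27,204,49.1
15,2019-02-09,1728,72.7
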