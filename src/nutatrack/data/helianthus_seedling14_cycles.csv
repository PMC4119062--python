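Numero,Start,End,Middle,Period,Length,Rate,Shape,Angle,Direction
1,2013-07-30 18:35,2013-07-30 21:00,2013-07-30 19:47,145,17,0.12,0.13,-70,?
2,2013-07-30 21:00,2013-07-30 23:10,2013-07-30 22:05,130,32,0.25,0.14,-78,CW
3,2013-07-30 23:10,2013-07-31 01:45,2013-07-31 00:27,155,48,0.31,0.16,-78,CW
4,2013-07-31 01:45,2013-07-31 04:10,2013-07-31 02:57,145,40,0.28,0.19,-52,CCW
5,2013-07-31 04:10,2013-07-31 06:35,2013-07-31 05:22,145,39,0.27,0.28,-23,CCW
6,2013-07-31 06:35,2013-07-31 09:00,2013-07-31 07:47,145,45,0.31,0.50,17,CCW
7,2013-07-31 09:00,2013-07-31 11:30,2013-07-31 10:15,150,51,0.34,0.36,61,CCW
8,2013-07-31 11:30,2013-07-31 14:10,2013-07-31 12:50,160,56,0.35,0.66,86,CCW
9,2013-07-31 14:10,2013-07-31 17:10,2013-07-31 15:40,180,84,0.47,0.96,-15,CCW
10,2013-07-31 17:10,2013-07-31 20:10,2013-07-31 18:40,180,96,0.54,0.78,26,CCW
11,2013-07-31 20:10,2013-07-31 23:05,2013-07-31 21:37,175,103,0.59,0.73,45,CCW
12,2013-07-31 23:05,2013-08-01 02:05,2013-08-01 00:35,180,118,0.66,0.93,-87,CCW
13,2013-08-01 02:05,2013-08-01 05:15,2013-08-01 03:40,190,120,0.63,0.79,20,CCW
14,2013-08-01 05:15,2013-08-01 08:30,2013-08-01 06:52,195,104,0.54,0.62,35,CCW
15,2013-08-01 08:30,2013-08-01 11:40,2013-08-01 10:05,190,82,0.43,0.59,71,CCW
16,2013-08-01 11:40,2013-08-01 14:45,2013-08-01 13:12,185,64,0.35,0.83,79,CCW
17,2013-08-01 14:45,2013-08-01 18:00,2013-08-01 16:22,195,73,0.37,0.73,-88,CCW
18,2013-08-01 18:00,2013-08-01 21:10,2013-08-01 19:35,190,69,0.36,0.58,-84,CCW
19,2013-08-01 21:10,2013-08-02 00:20,2013-08-01 22:45,190,76,0.40,0.55,-52,CCW
20,2013-08-02 00:20,2013-08-02 04:00,2013-08-02 02:10,220,98,0.44,0.62,-41,CCW
21,2013-08-02 04:00,2013-08-02 08:00,2013-08-02 06:00,240,108,0.45,0.60,-4,CCW
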