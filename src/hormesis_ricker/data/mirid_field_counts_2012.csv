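plot_id,date,count,sprayed,threshold
South 1,2012-05-28,0,0,1
South 1,2012-06-03,0,0,1
South 1,2012-06-07,0,0,1
South 1,2012-06-12,0,0,1
South 1,2012-06-18,0,0,1
South 1,2012-06-22,0,0,1
South 1,2012-06-27,0,0,1
South 1,2012-07-02,0,0,1
South 1,2012-07-07,0,0,1
South 1,2012-07-12,0,0,1
South 1,2012-07-17,0,0,1
South 1,2012-07-22,0,0,1
South 1,2012-07-27,6,1,1
South 1,2012-08-02,6,1,1
South 1,2012-08-07,7,1,1
South 1,2012-08-11,31,1,1
South 1,2012-08-16,38,1,1
South 1,2012-08-21,26,1,1
South 1,2012-08-26,23,1,1
South 1,2012-08-31,2,1,1
South 1,2012-09-05,3,1,1
South 2,2012-05-28,0,0,2
South 2,2012-06-03,0,0,2
South 2,2012-06-07,0,0,2
South 2,2012-06-12,0,0,2
South 2,2012-06-18,0,0,2
South 2,2012-06-22,0,0,2
South 2,2012-06-27,1,0,2
South 2,2012-07-02,0,0,2
South 2,2012-07-07,0,0,2
South 2,2012-07-12,0,0,2
South 2,2012-07-17,2,1,2
South 2,2012-07-22,3,1,2
South 2,2012-07-27,8,1,2
South 2,2012-08-02,18,1,2
South 2,2012-08-07,10,1,2
South 2,2012-08-11,12,1,2
South 2,2012-08-16,42,1,2
South 2,2012-08-21,28,1,2
South 2,2012-08-26,30,1,2
South 2,2012-08-31,9,1,2
South 2,2012-09-05,5,1,2
South 3,2012-05-28,0,0,5
South 3,2012-06-03,0,0,5
South 3,2012-06-07,0,0,5
South 3,2012-06-12,0,0,5
South 3,2012-06-18,0,0,5
South 3,2012-06-22,0,0,5
South 3,2012-06-27,0,0,5
South 3,2012-07-02,0,0,5
South 3,2012-07-07,1,0,5
South 3,2012-07-12,0,0,5
South 3,2012-07-17,7,1,5
South 3,2012-07-22,5,1,5
South 3,2012-07-27,5,1,5
South 3,2012-08-02,7,1,5
South 3,2012-08-07,12,1,5
South 3,2012-08-11,9,1,5
South 3,2012-08-16,18,1,5
South 3,2012-08-21,29,1,5
South 3,2012-08-26,19,1,5
South 3,2012-08-31,8,1,5
South 3,2012-09-05,2,0,5
South 4,2012-05-28,0,0,10
South 4,2012-06-03,0,0,10
South 4,2012-06-07,0,0,10
South 4,2012-06-12,2,0,10
South 4,2012-06-18,0,0,10
South 4,2012-06-22,0,0,10
South 4,2012-06-27,0,0,10
South 4,2012-07-02,0,0,10
South 4,2012-07-07,0,0,10
South 4,2012-07-12,0,0,10
South 4,2012-07-17,3,0,10
South 4,2012-07-22,5,0,10
South 4,2012-07-27,1,0,10
South 4,2012-08-02,16,0,10
South 4,2012-08-07,12,1,10
South 4,2012-08-11,23,1,10
South 4,2012-08-16,16,1,10
South 4,2012-08-21,28,1,10
South 4,2012-08-26,14,1,10
South 4,2012-08-31,5,0,10
South 4,2012-09-05,3,0,10
South 5,2012-05-28,0,0,20
South 5,2012-06-03,0,0,20
South 5,2012-06-07,0,0,20
South 5,2012-06-12,0,0,20
South 5,2012-06-18,0,0,20
South 5,2012-06-22,0,0,20
South 5,2012-06-27,0,0,20
South 5,2012-07-02,1,0,20
South 5,2012-07-07,0,0,20
South 5,2012-07-12,0,0,20
South 5,2012-07-17,9,0,20
South 5,2012-07-22,3,0,20
South 5,2012-07-27,6,0,20
South 5,2012-08-02,7,0,20
South 5,2012-08-07,5,0,20
South 5,2012-08-11,51,1,20
South 5,2012-08-16,51,1,20
South 5,2012-08-21,27,1,20
South 5,2012-08-26,24,1,20
South 5,2012-08-31,3,0,20
South 5,2012-09-05,4,0,20
South 6,2012-05-28,0,0,40
South 6,2012-06-03,0,0,40
South 6,2012-06-07,0,0,40
South 6,2012-06-12,0,0,40
South 6,2012-06-18,0,0,40
South 6,2012-06-22,0,0,40
South 6,2012-06-27,0,0,40
South 6,2012-07-02,0,0,40
South 6,2012-07-07,0,0,40
South 6,2012-07-12,2,0,40
South 6,2012-07-17,2,0,40
South 6,2012-07-22,1,0,40
South 6,2012-07-27,3,0,40
South 6,2012-08-02,16,1,40
South 6,2012-08-07,13,0,40
South 6,2012-08-11,49,1,40
South 6,2012-08-16,80,1,40
South 6,2012-08-21,41,1,40
South 6,2012-08-26,19,0,40
South 6,2012-08-31,55,0,40
South 6,2012-09-05,3,0,40
South 7,2012-05-28,0,0,60
South 7,2012-06-03,0,0,60
South 7,2012-06-07,0,0,60
South 7,2012-06-12,0,0,60
South 7,2012-06-18,0,0,60
South 7,2012-06-22,0,0,60
South 7,2012-06-27,0,0,60
South 7,2012-07-02,0,0,60
South 7,2012-07-07,0,0,60
South 7,2012-07-12,1,0,60
South 7,2012-07-17,32,0,60
South 7,2012-07-22,3,0,60
South 7,2012-07-27,10,0,60
South 7,2012-08-02,20,0,60
South 7,2012-08-07,14,0,60
South 7,2012-08-11,22,0,60
South 7,2012-08-16,63,1,60
South 7,2012-08-21,28,0,60
South 7,2012-08-26,24,0,60
South 7,2012-08-31,5,0,60
South 7,2012-09-05,3,0,60
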