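{
 "levels": [
  0.5,
  0.7,
  0.9
 ],
 "rows": [
  [
   0.8534265795302787,
   0.024828191033964078,
   0.1217452294357574
  ],
  [
   0.8332886215085777,
   0.135287917952621,
   0.03142346053880117
  ],
  [
   0.2551563325942638,
   0.4194037485922878,
   0.3254399188134485
  ]
 ],
 "r_as": [
  [
   -0.6762278305018379,
   -0.06764508315994533,
   1.463517034064711
  ],
  [
   1.3823870288858209,
   -1.364196867850226,
   0.3721080630057423
  ],
  [
   -1.1914308540327823,
   0.4112611747989927,
   0.1393582403045568
  ]
 ],
 "terminal": [
  1.072796219409526,
  0.010746617566720351,
  4.331831572126434
 ],
 "gamma": [
  3.491736131423472,
  3.133980136172164,
  0.07278063688326021
 ],
 "d_st": [
  [
   0.5207995084240662,
   0.5207995084240662,
   0.5207995084240662
  ],
  [
   0.5207995084240662,
   0.5207995084240662,
   0.5207995084240662
  ],
  [
   0.5207995084240662,
   0.5207995084240662,
   0.5207995084240662
  ]
 ]
}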