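{
 "master_seed": 20160913,
 "right_types": [
  {
   "bo_side": "right",
   "facilitatory": [
    [
     7.945308076030329,
     26.22607224498237,
     10.917516947591686,
     0.3437392707355688
    ],
    [
     -2.6049785890130366,
     26.50388832509013,
     3.647333877325222,
     0.3054274261517223
    ],
    [
     3.4359096994965554,
     17.58667074715727,
     10.39574487927366,
     0.3508333031127088
    ]
   ],
   "suppressive": [
    [
     7.228029317995286,
     -28.10826167582203,
     11.94402084460933,
     1.0
    ]
   ]
  },
  {
   "bo_side": "right",
   "facilitatory": [
    [
     -5.6309621008746475,
     30.98368851755117,
     4.2824054552797275,
     0.6175690369219371
    ],
    [
     26.728853791389454,
     41.34801592393999,
     8.021500745508476,
     0.3824309630780628
    ]
   ],
   "suppressive": [
    [
     9.192773432788265,
     -12.767548022599907,
     8.46526066582759,
     0.25896397863676707
    ],
    [
     -17.327325525889854,
     -41.705128427420824,
     7.830217670074733,
     0.2981954935790683
    ],
    [
     -20.50860253135858,
     -40.98119967799318,
     10.96206038411681,
     0.4428405277841646
    ]
   ]
  },
  {
   "bo_side": "right",
   "facilitatory": [
    [
     -19.95191238627185,
     35.95556929921527,
     10.31264445318773,
     1.0
    ]
   ],
   "suppressive": [
    [
     -12.719828889413943,
     -19.976232552603076,
     10.294985140385654,
     1.0
    ]
   ]
  },
  {
   "bo_side": "right",
   "facilitatory": [
    [
     6.147241425376336,
     19.60080771627752,
     11.275652291812454,
     0.41863508335634186
    ],
    [
     -17.386870177812956,
     22.943544102585236,
     5.761999415289789,
     0.21995773903388635
    ],
    [
     -15.199118459354397,
     34.49936435467607,
     6.144290574466598,
     0.36140717760977176
    ]
   ],
   "suppressive": [
    [
     -13.410579614024776,
     -26.28039378053025,
     4.007140285434288,
     0.3510422769566476
    ],
    [
     23.225859804132483,
     -27.931038380489444,
     9.09518178514205,
     0.30420787569283503
    ],
    [
     7.687958409224237,
     -29.81039808805412,
     11.45679258993085,
     0.34474984735051756
    ]
   ]
  },
  {
   "bo_side": "right",
   "facilitatory": [
    [
     -18.55783349452346,
     42.33457784273475,
     9.270959419140691,
     1.0
    ]
   ],
   "suppressive": [
    [
     -23.26871159518338,
     -17.680958873264952,
     8.744989718371414,
     0.5108360488931387
    ],
    [
     12.457681077416765,
     -13.287029125324011,
     10.22728855922325,
     0.4891639511068613
    ]
   ]
  },
  {
   "bo_side": "right",
   "facilitatory": [
    [
     -11.4264191877731,
     38.32962649328522,
     8.647279811670089,
     1.0
    ]
   ],
   "suppressive": [
    [
     12.84767036610225,
     -10.986980007160652,
     9.352880411223628,
     1.0
    ]
   ]
  },
  {
   "bo_side": "right",
   "facilitatory": [
    [
     4.952773888690189,
     42.060502590577435,
     5.329237356277947,
     0.58174548059306
    ],
    [
     21.507562439277457,
     32.71087095470127,
     4.86342919304914,
     0.4182545194069399
    ]
   ],
   "suppressive": [
    [
     -26.929150578480243,
     -20.81186597835023,
     4.181784453051469,
     0.583809697531879
    ],
    [
     19.427344003053364,
     -19.12076358728855,
     7.134754409289677,
     0.4161903024681211
    ]
   ]
  },
  {
   "bo_side": "right",
   "facilitatory": [
    [
     13.924097984327233,
     25.336154852124242,
     6.48897693109417,
     1.0
    ]
   ],
   "suppressive": [
    [
     -21.03063867260027,
     -8.029211175670895,
     5.343836125830648,
     0.5940637385600193
    ],
    [
     10.327279064510016,
     -18.816000056374595,
     5.229853969634878,
     0.4059362614399807
    ]
   ]
  },
  {
   "bo_side": "right",
   "facilitatory": [
    [
     21.736356898887514,
     27.893526282517506,
     3.4650036215565656,
     0.3107857214291722
    ],
    [
     -20.345522548898003,
     41.69293085306117,
     8.1421238037659,
     0.36146891276613735
    ],
    [
     -16.709892487257378,
     25.322505859196184,
     9.613418669200875,
     0.3277453658046905
    ]
   ],
   "suppressive": [
    [
     23.914982224811126,
     -20.118967374153804,
     4.5124485731206905,
     1.0
    ]
   ]
  },
  {
   "bo_side": "right",
   "facilitatory": [
    [
     -2.5713323626219733,
     35.38743214009103,
     5.569868148312987,
     0.3393455197595346
    ],
    [
     -11.219075504655198,
     19.134799952550175,
     5.777593123491791,
     0.3122539766628801
    ],
    [
     21.34392235865741,
     44.600118820257805,
     6.077906611091288,
     0.3484005035775853
    ]
   ],
   "suppressive": [
    [
     -9.996696909666948,
     -6.852525577857929,
     11.683377839270927,
     0.3275747647869718
    ],
    [
     15.281619813790272,
     -20.788856197884414,
     8.394805238955906,
     0.32188426172381057
    ],
    [
     27.446953635778975,
     -36.87213318819111,
     4.1575358988886535,
     0.35054097348921764
    ]
   ]
  }
 ]
}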