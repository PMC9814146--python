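27
synthetic fenchone-like conformer (distance-geometry embedding; stand-in, not the experimental geometry)
C        2.0246133406      -0.0943518393       1.4590356586
C        1.2219312894       0.0973361303       0.1692518108
C        2.1390097633       0.5875022165      -0.9492829473
C        0.0613232179       1.0629438741       0.4007371564
O        0.1734900282       2.2506945542       0.6652974011
C       -1.2574713123       0.3145429093       0.2156643674
C       -2.4497265904       0.9440279232       0.8893689350
C       -1.3935300275       0.0665878976      -1.2967501184
C       -0.3329020879      -1.0216337689      -1.5611006487
C        0.3767575737      -1.1690017665      -0.1958481184
C       -0.8387527187      -1.0616398676       0.7400611505
H        2.7521380584      -0.9054833085       1.3474082874
H        1.3920317107      -0.3245700579       2.3215390188
H        2.5742922917       0.8186241384       1.7163576627
H        1.5805571181       0.9815413844      -1.8045758569
H        2.7754981281       1.4097626455      -0.6017249953
H        2.7929510836      -0.2172608666      -1.3010791617
H       -2.2614190714       1.1036187571       1.9566383310
H       -2.6790645923       1.9201156349       0.4484804702
H       -3.3382833066       0.3115389709       0.7936706065
H       -1.1901638362       0.9679131182      -1.8855043191
H       -2.3891557283      -0.3041155681      -1.5646011838
H        0.3358245877      -0.7663208925      -2.3865093975
H       -0.8313728086      -1.9617104218      -1.8282323875
H        0.9348953478      -2.1045271243      -0.1065369833
H       -1.5907292452      -1.8374821735       0.5548334447
H       -0.5827422139      -1.0686524994       1.8034018165
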