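 1.8609595825979017292,-0.6808710998199428710,-0.4834183632344548620, 0.7588185320051554772,-2.4997133603654129175
 1.9806243135174947945, 2.4155099703708491354, 1.6037291584957227286, 2.3075760841876666873, 0.7947294852439603652
 2.0937853220314832647, 1.6475394501249107648, 0.5516485734830665066, 1.2345175569641908542, 0.0513030335626368239
-0.0189905097162643699, 2.1509626424643135678,-1.3843019648739545158, 0.9864318983736359847, 1.2423559992325752255
 1.5797333942657374450, 2.3639134606283560558, 1.0517934930570480567, 0.6744161999871083335, 1.3790215585220404471
 0.0312232329687929244, 2.4433333371165257830, 0.5616687469312007241, 0.7248636516331310453, 0.2752900849284479756
 0.2951463456605230018,-0.3218124715172873129, 2.0049440615917490938,-0.5530552194806304112, 0.3448169679511285945
 1.3524709347093424316, 0.8552701684801786719, 0.7536930778535517739, 0.9755755080768289123, 0.3413824084008423299
 0.1550805249793310026,-1.4590382307500688874,-0.1573836197119916624, 2.1416892735714876395,-1.0685592246341830691
 1.2320191084695693018, 1.0541014202373217845,-0.5246936183021162492,-0.2678845472764102009, 2.1803867113224697505
 2.0313065967355612429,-0.3032170180758390621, 0.0233692415382354968, 0.3568601846812811118,-0.5217198821941924081
 2.3587124989377628026, 2.4861344156048499343, 2.1714644379928911277, 3.6453255653147440540,-0.2658970482411363578
 0.8672363849308254435, 1.0657121166137346613,-0.0550608797457881050, 0.0758461878394366407,-0.7678682632084883330
 3.1034457922296621035, 3.6302030020193649662,-0.2373905147065186183, 0.7103263049272395824,-0.0832542014960306331
 0.1482392150480188464, 0.5128816479351179236, 0.3433753329221062023, 0.8946488386933524328, 1.6235246916052996635
 2.2868012208502701554, 2.2495539347138793218,-0.0011123312565843313, 3.2964972733855635312,-1.1041884452299701724
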