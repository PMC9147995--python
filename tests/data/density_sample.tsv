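x
0.0095744943226810479
0.0026064566355553011
0.0036114149791290819
0.0041754140977263952
0.0030586533177610334
0.0031054401095437847
0.0064962786805811022
0.0047660895482256969
0.0053053152525644673
0.0093799562146587596
0.0057139724606580450
0.0104335035662614494
0.0095629038519791133
0.0056480410802770319
0.0087921341336198618
0.0059353610226433959
0.0032123985538291128
0.0043853434009256112
0.0049903551554648590
0.0069763282989998895
0.0066795007192481425
0.0064106836618110005
0.0076119294416233749
0.0022240075668142996
0.0075458337285104742
0.0053683855424715345
0.0065045597914800664
0.0061834901049254536
0.0030338948084579582
0.0044478720897759881
0.0032582979548628176
0.0064374211061684911
0.0052213057555386723
0.0048430664640565918
0.0041590190813160042
0.0038757482474294684
0.0069950268895106107
0.0027897398823734745
0.0047154243384508300
0.0056299898097758264
0.0074371010690146956
0.0036013658426289723
0.0044291344969425474
0.0023768946547812284
0.0042179751371014835
0.0041969467738100560
0.0077010351618459066
0.0061823800541784416
0.0052010509112571379
0.0068621439910401937
0.0044745153028669347
0.0049846637905746720
0.0057343060130912692
0.0084143250902752129
0.0064474805250567596
0.0059620720974158346
0.0018642635115494973
0.0056365005669616556
0.0053319829013547008
0.0032001847407436570
0.1007637147386057502
0.1015915527826272841
0.1054367418470969903
0.1070480735261304800
0.1031896914255711062
0.1110924978897105675
0.1076915419465711288
0.1115347367477893675
0.1126068350268093765
0.1070062350657232514
0.1043262716084595587
0.0907739828174307928
0.0938441579336908166
0.0913334031174862643
0.0836048291281886319
0.0867416075615659032
0.0911096327236202985
0.0944239766969788702
0.0993759769116165231
0.1242269297715942744
0.1034258535014730002
0.1000424823625213067
0.1002921984200165068
0.0960657657087869848
0.0920729543721107296
0.0968829813470482859
0.0965393140821914075
0.0969539241175467609
0.0821410651255548296
0.1058727467185796994
0.1163579443444659189
0.0935457652636560444
0.1061899216878734037
0.1023639359840132212
0.1084650089875164453
0.0942635426115030761
0.1111799320399617375
0.0845999886806697993
0.0956187610069991478
0.0984932702910355229
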