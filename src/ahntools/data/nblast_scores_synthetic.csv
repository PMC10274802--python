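dist_lower,0-0.1,0.1-0.2,0.2-0.3,0.3-0.4,0.4-0.5,0.5-0.6,0.6-0.7,0.7-0.8,0.8-0.9,0.9-1
0,-0.344239843385719,-0.032719530157157006,0.2788007830714049,0.590321096299967,0.9018414095285288,1.213361722757091,1.524882035985653,1.8364023492142145,2.147922662442777,2.4594429756713385
2.5,-0.40552668945179704,-0.21658006835539112,-0.02763344725898531,0.1613131738374206,0.3502597949338264,0.5392064160302323,0.7281530371266385,0.917099658223044,1.10604627931945,1.2949929004158558
5,-0.44269904062796195,-0.32809712188388596,-0.2134952031398099,-0.09889328439573386,0.015708634348342132,0.13031055309241824,0.24491247183649434,0.3595143905805702,0.47411630932464643,0.5887182280687222
7.5,-0.465245211309911,-0.3957356339297329,-0.32622605654955483,-0.2567164791693768,-0.18720690178919874,-0.11769732440902064,-0.04818774702884254,0.02132183035133539,0.09083140773151355,0.16034098511169148
10,-0.47892015508762714,-0.43676046526288137,-0.39460077543813565,-0.35244108561338994,-0.3102813957886442,-0.26812170596389845,-0.22596201613915268,-0.18380232631440702,-0.14164263648966124,-0.09948294666491553
12.5,-0.4872144277586585,-0.4616432832759755,-0.43607213879329243,-0.4105009943106094,-0.3849298498279264,-0.35935870534524333,-0.3337875608625603,-0.3082164163798773,-0.28264527189719424,-0.25707412741451124
15,-0.49224515843365557,-0.47673547530096677,-0.46122579216827797,-0.44571610903558917,-0.43020642590290037,-0.41469674277021157,-0.39918705963752277,-0.38367737650483397,-0.36816769337214517,-0.35265801023945637
17.5,-0.4952964508287982,-0.48588935248639453,-0.47648225414399087,-0.46707515580158726,-0.4576680574591836,-0.44826095911678,-0.4388538607743763,-0.42944676243197266,-0.42003966408956905,-0.4106325657471654
20,-0.49714715321820013,-0.49144145965460045,-0.4857357660910007,-0.48003007252740104,-0.47432437896380136,-0.46861868540020163,-0.46291299183660195,-0.4572072982730022,-0.45150160470940254,-0.44579591114580286
22.5,-0.49826966095937586,-0.49480898287812763,-0.49134830479687935,-0.48788762671563113,-0.48442694863438285,-0.4809662705531346,-0.47750559247188634,-0.4740449143906381,-0.47058423630938984,-0.4671235582281416
25,-0.49895049632016375,-0.4968514889604912,-0.49475248160081864,-0.4926534742411461,-0.4905544668814735,-0.48845545952180097,-0.4863564521621284,-0.48425744480245586,-0.4821584374427833,-0.48005943008311075
27.5,-0.4993634438406981,-0.4980903315220942,-0.4968172192034903,-0.4955441068848865,-0.4942709945662826,-0.4929978822476787,-0.4917247699290749,-0.490451657610471,-0.4891785452918671,-0.4879054329732633
30,-0.49961390917275444,-0.4988417275182634,-0.4980695458637723,-0.4972973642092812,-0.4965251825547901,-0.49575300090029906,-0.49498081924580795,-0.4942086375913169,-0.4934364559368258,-0.4926642742823347
32.5,-0.49976582407584175,-0.4992974722275253,-0.49882912037920885,-0.49836076853089234,-0.4978924166825759,-0.49742406483425944,-0.49695571298594293,-0.4964873611376265,-0.49601900928931003,-0.4955506574409935
35,-0.4998579651222315,-0.4995738953666945,-0.4992898256111575,-0.49900575585562046,-0.49872168610008344,-0.4984376163445464,-0.4981535465890094,-0.4978694768334724,-0.49758540707793536,-0.49730133732239834
37.5,-0.4999138514918849,-0.4997415544756546,-0.4995692574594243,-0.49939696044319404,-0.49922466342696376,-0.4990523664107335,-0.4988800693945032,-0.49870777237827296,-0.4985354753620427,-0.4983631783458124
40,-0.49994774828853966,-0.499843244865619,-0.4997387414426983,-0.4996342380197777,-0.499529734596857,-0.49942523117393633,-0.49932072775101566,-0.499216224328095,-0.4991117209051743,-0.4990072174822537
42.5,-0.49996830773497686,-0.4999049232049306,-0.49984153867488423,-0.49977815414483795,-0.49971476961479167,-0.4996513850847453,-0.49958800055469904,-0.49952461602465276,-0.4994612314946065,-0.49939784696456013
45,-0.4999807776695877,-0.4999423330087632,-0.4999038883479386,-0.49986544368711405,-0.49982699902628946,-0.49978855436546493,-0.4997501097046404,-0.4997116650438158,-0.4996732203829913,-0.4996347757221667
47.5,-0.4999883410672538,-0.4999650232017615,-0.49994170533626914,-0.49991838747077677,-0.49989506960528446,-0.4998717517397921,-0.4998484338742997,-0.4998251160088074,-0.49980179814331505,-0.4997784802778227
50,-0.4999929284998299,-0.49997878549948976,-0.49996464249914957,-0.49995049949880943,-0.49993635649846924,-0.4999222134981291,-0.49990807049778896,-0.49989392749744876,-0.4998797844971086,-0.49986564149676843
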