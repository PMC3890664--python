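taxon,character,mean,sd,n
Ancash,SVL,57.0,4.0,29
Ancash,AGL,26.5,3.4,29
Ancash,HL,12.4,1.1,29
Ancash,HW,10.3,1.1,29
Ancash,SL,5.2,0.5,29
Ancash,FoL,16.2,1.5,29
Ancash,HiL,25.8,1.8,29
Ancash,AMH,2.2,0.26,29
Ancash,AMW,1.0,0.2,29
Ancash,RH,1.0,0.1,29
Ancash,RW,2.7,0.3,29
Ayacucho,SVL,55.6,3.1,16
Ayacucho,AGL,25.9,3.9,16
Ayacucho,HL,11.4,0.8,16
Ayacucho,HW,9.4,0.8,16
Ayacucho,SL,4.4,0.3,16
Ayacucho,FoL,15.7,1.2,16
Ayacucho,HiL,24.2,2.5,16
Ayacucho,AMH,2.1,0.22,16
Ayacucho,AMW,1.1,0.1,16
Ayacucho,RH,1.0,0.1,16
Ayacucho,RW,2.5,0.3,16
Cusco,SVL,45.4,4.4,17
Cusco,AGL,22.6,3.6,17
Cusco,HL,10.6,1.0,17
Cusco,HW,8.2,0.7,17
Cusco,SL,4.0,0.5,17
Cusco,FoL,15.7,1.3,17
Cusco,HiL,23.4,2.1,17
Cusco,AMH,1.8,0.3,17
Cusco,AMW,1.0,0.1,17
Cusco,RH,1.0,0.3,17
Cusco,RW,2.6,0.1,17
tacnae,SVL,48.6,3.2,36
tacnae,AGL,21.8,2.7,36
tacnae,HL,10.7,0.7,36
tacnae,HW,9.6,0.8,36
tacnae,SL,4.5,0.4,36
tacnae,FoL,15.7,1.4,36
tacnae,HiL,24.6,2.2,36
tacnae,AMH,1.9,0.2,36
tacnae,AMW,1.2,0.1,36
tacnae,RH,1.1,0.2,36
tacnae,RW,2.2,0.2,36
walkeri,SVL,54.5,4.6,74
walkeri,AGL,25.3,3.4,74
walkeri,HL,12.2,0.9,74
walkeri,HW,9.6,0.9,74
walkeri,SL,5.1,0.5,74
walkeri,FoL,16.7,1.5,74
walkeri,HiL,25.2,2.5,74
walkeri,AMH,2.1,0.3,74
walkeri,AMW,1.2,0.2,74
walkeri,RH,1.0,0.1,74
walkeri,RW,2.6,0.3,74
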