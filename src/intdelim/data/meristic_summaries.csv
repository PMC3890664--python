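taxon,character,mean,sd,n
Ancash,MBS,56.8,6.1,32
Ancash,DTS,56.1,7.2,32
Ancash,DHS,14.6,2.1,32
Ancash,VS,79.6,4.5,32
Ancash,SCI,7.9,1.4,32
Ayacucho,MBS,50.6,3.0,30
Ayacucho,DTS,46.4,3.6,30
Ayacucho,DHS,12.7,1.8,30
Ayacucho,VS,77.7,4.1,30
Ayacucho,SCI,7.6,1.4,30
Cusco,MBS,46.5,3.4,18
Cusco,DTS,47.2,3.6,18
Cusco,DHS,13.5,1.5,18
Cusco,VS,72.8,6.4,18
Cusco,SCI,6.4,1.2,18
tacnae,MBS,48.1,4.1,42
tacnae,DTS,47.0,4.1,42
tacnae,DHS,14.0,1.7,42
tacnae,VS,76.3,6.5,42
tacnae,SCI,7.0,1.0,42
walkeri,MBS,53.8,3.6,79
walkeri,DTS,54.4,4.6,79
walkeri,DHS,13.7,1.7,79
walkeri,VS,80.7,5.2,79
walkeri,SCI,7.1,1.0,79
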