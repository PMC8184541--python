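outcome,population,age,probability_pct
mof,Botswana,50,1.6
mof,Botswana,55,1.7
mof,Botswana,60,1.7
mof,Botswana,65,1.7
mof,Botswana,70,1.9
mof,Botswana,75,2.3
mof,Botswana,80,2.7
mof,Botswana,85,3.3
mof,Botswana,90,3.8
mof,"South Africa, Black",50,2.6
mof,"South Africa, Black",55,3.1
mof,"South Africa, Black",60,3.7
mof,"South Africa, Black",65,4.3
mof,"South Africa, Black",70,5.1
mof,"South Africa, Black",75,6.2
mof,"South Africa, Black",80,7.2
mof,"South Africa, Black",85,8.7
mof,"South Africa, Black",90,9.8
mof,"South Africa, Coloured",50,3.1
mof,"South Africa, Coloured",55,4.6
mof,"South Africa, Coloured",60,6.3
mof,"South Africa, Coloured",65,7.6
mof,"South Africa, Coloured",70,9.1
mof,"South Africa, Coloured",75,11
mof,"South Africa, Coloured",80,13
mof,"South Africa, Coloured",85,16
mof,"South Africa, Coloured",90,18
mof,Morocco,50,2.1
mof,Morocco,55,3.1
mof,Morocco,60,4.5
mof,Morocco,65,5.8
mof,Morocco,70,7.0
mof,Morocco,75,8.2
mof,Morocco,80,9.1
mof,Morocco,85,10
mof,Morocco,90,10
mof,Tunisia,50,1.0
mof,Tunisia,55,1.2
mof,Tunisia,60,1.6
mof,Tunisia,65,2.0
mof,Tunisia,70,2.3
mof,Tunisia,75,2.4
mof,Tunisia,80,2.6
mof,Tunisia,85,3.0
mof,Tunisia,90,3.4
mof,US Black,50,3.5
mof,US Black,55,5.3
mof,US Black,60,6.9
mof,US Black,65,8.2
mof,US Black,70,9.9
mof,US Black,75,12
mof,US Black,80,16
mof,US Black,85,18
mof,US Black,90,16
hip,Botswana,50,0.2
hip,Botswana,55,0.2
hip,Botswana,60,0.3
hip,Botswana,65,0.5
hip,Botswana,70,0.8
hip,Botswana,75,1.1
hip,Botswana,80,1.5
hip,Botswana,85,1.7
hip,Botswana,90,1.5
hip,"South Africa, Black",50,0.5
hip,"South Africa, Black",55,0.7
hip,"South Africa, Black",60,1.0
hip,"South Africa, Black",65,1.4
hip,"South Africa, Black",70,1.9
hip,"South Africa, Black",75,2.3
hip,"South Africa, Black",80,2.7
hip,"South Africa, Black",85,3.6
hip,"South Africa, Black",90,4.4
hip,"South Africa, Coloured",50,0.5
hip,"South Africa, Coloured",55,0.9
hip,"South Africa, Coloured",60,1.4
hip,"South Africa, Coloured",65,2.1
hip,"South Africa, Coloured",70,2.9
hip,"South Africa, Coloured",75,3.7
hip,"South Africa, Coloured",80,4.7
hip,"South Africa, Coloured",85,6.9
hip,"South Africa, Coloured",90,9.3
hip,Morocco,50,0.3
hip,Morocco,55,0.6
hip,Morocco,60,1.0
hip,Morocco,65,1.6
hip,Morocco,70,2.2
hip,Morocco,75,2.9
hip,Morocco,80,3.7
hip,Morocco,85,5.1
hip,Morocco,90,6.4
hip,Tunisia,50,0.1
hip,Tunisia,55,0.2
hip,Tunisia,60,0.4
hip,Tunisia,65,0.6
hip,Tunisia,70,0.7
hip,Tunisia,75,0.8
hip,Tunisia,80,1.0
hip,Tunisia,85,1.2
hip,Tunisia,90,1.4
hip,US Black,50,0.3
hip,US Black,55,0.5
hip,US Black,60,0.9
hip,US Black,65,1.4
hip,US Black,70,2.2
hip,US Black,75,3.6
hip,US Black,80,5.3
hip,US Black,85,6.6
hip,US Black,90,6.3
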