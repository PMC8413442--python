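table_id,kind,lower,upper,category,code,score
Pr,binned,,100,,,1.7
Pr,binned,100,200,,,3.4
Pr,binned,200,400,,,5.1
Pr,binned,400,600,,,6.8
Pr,binned,600,800,,,8.5
Pr,binned,800,,,,10.0
T,binned,,-5,,,2.0
T,binned,-5,-3,,,4.0
T,binned,-3,0,,,6.0
T,binned,0,10,,,8.0
T,binned,10,,,,10.0
Di,binned,,0.05,,,2.0
Di,binned,0.05,0.2,,,4.0
Di,binned,0.2,0.5,,,6.0
Di,binned,0.5,0.65,,,8.0
Di,binned,0.65,,,,10.0
Al,binned,,2300,,,10.0
Al,binned,2300,3600,,,8.0
Al,binned,3600,4400,,,6.0
Al,binned,4400,5000,,,4.0
Al,binned,5000,,,,2.0
Par,binned,,3300,,,2.0
Par,binned,3300,3500,,,4.0
Par,binned,3500,3700,,,6.0
Par,binned,3700,3800,,,8.0
Par,binned,3800,,,,10.0
At,binned,,500,,,1.25
At,binned,500,1000,,,2.50
At,binned,1000,2000,,,3.75
At,binned,2000,3000,,,5.00
At,binned,3000,4000,,,6.25
At,binned,4000,5000,,,7.50
At,binned,5000,6000,,,8.75
At,binned,6000,,,,10.00
Sd,binned,,10,,,2.5
Sd,binned,10,30,,,5.0
Sd,binned,30,100,,,7.5
Sd,binned,100,,,,10.0
St,binned,,0.25,,,2.5
St,binned,0.25,0.5,,,5.0
St,binned,0.5,0.75,,,7.5
St,binned,0.75,,,,10.0
Sei,categorical,,,Severe,1,1.7
Sei,categorical,,,Extreme slightly,2,3.4
Sei,categorical,,,Strength,3,5.1
Sei,categorical,,,Moderate,4,6.8
Sei,categorical,,,Mild,5,8.5
Sei,categorical,,,Slightly,6,10.0
Som,binned,,0.8,,,2.0
Som,binned,0.8,2.7,,,4.0
Som,binned,2.7,5,,,6.0
Som,binned,5,9.2,,,8.0
Som,binned,9.2,,,,10.0
Sm,binned,,0.06,,,2.0
Sm,binned,0.06,0.077,,,4.0
Sm,binned,0.077,0.098,,,6.0
Sm,binned,0.098,0.122,,,8.0
Sm,binned,0.122,,,,10.0
Vc,binned,,5,,,2.0
Vc,binned,5,50,,,4.0
Vc,binned,50,100,,,6.0
Vc,binned,100,158,,,8.0
Vc,binned,158,,,,10.0
Vr,binned,,0.005,,,2.0
Vr,binned,0.005,0.01,,,4.0
Vr,binned,0.01,0.02,,,6.0
Vr,binned,0.02,0.22,,,8.0
Vr,binned,0.22,,,,10.0
NPP,binned,,50,,,2.0
NPP,binned,50,100,,,4.0
NPP,binned,100,500,,,6.0
NPP,binned,500,1000,,,8.0
NPP,binned,1000,,,,10.0
Vrr,categorical,,,"Desert, swamp, others",1,2.0
Vrr,categorical,,,"Grassland, grass, meadow, cultivated vegetation",2,6.0
Vrr,categorical,,,Shrub,3,8.0
Vrr,categorical,,,Woodland,4,10.0
A,categorical,,,Sunny slope,1,2.5
A,categorical,,,Half sunny slope,2,5.0
A,categorical,,,Half shady slope,3,7.5
A,categorical,,,Shady slope,4,10.0
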