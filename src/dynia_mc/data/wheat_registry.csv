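name,description,lower,upper,distribution,integer_flag,units
X1,Soil water depletion factors (p) adjusted by ETo (0=no; 1=yes),0,1,uniform,1,flag
X2,Base temperature below which crop development does not progress,0,5,uniform,0,degC
X3,Upper temperature above which crop development no longer increases,22,30,uniform,0,degC
X4,Soil water depletion factor for canopy expansion (p-exp) - upper threshold,0.15,0.35,uniform,0,fraction TAW
X5,Soil water depletion factor for canopy expansion (p-exp) - lower threshold,0.55,0.75,uniform,0,fraction TAW
X6,Shape factor for water stress coefficient for canopy expansion (0.0 = straight line),0,6,uniform,0,-
X7,Soil water depletion fraction for stomatal control (p-sto) - upper threshold,0.45,0.70,uniform,0,fraction TAW
X8,Shape factor for water stress coefficient for stomatal control (0.0 = straight line),0,6,uniform,0,-
X9,Soil water depletion factor for canopy senescence (p-sen) - upper threshold,0.60,0.90,uniform,0,fraction TAW
X10,Shape factor for water stress coefficient for canopy senescence (0.0 = straight line),0,6,uniform,0,-
X11,Soil water depletion factor for pollination (p-pol) - upper threshold,0.80,0.95,uniform,0,fraction TAW
X12,Anaerobiotic point (vol% below saturation at which deficient aeration occurs),2,10,uniform,1,vol%
X13,Minimum air temperature below which pollination starts to fail (cold stress),2,10,uniform,1,degC
X14,Maximum air temperature above which pollination starts to fail (heat stress),30,40,uniform,1,degC
X15,Minimum growing degrees required for full biomass production,1200,1700,uniform,1,degC day
X16,Electrical conductivity of saturation extract at which crop starts to be affected by salinity,2,8,uniform,1,dS/m
X17,Electrical conductivity of saturation extract at which crop can no longer grow,10,20,uniform,1,dS/m
X18,Crop coefficient when canopy is complete but prior to senescence (KcTr),1.00,1.20,uniform,0,-
X19,Decline of crop coefficient as a result of ageing or nitrogen deficiency,0.10,0.50,uniform,0,%/day
X20,Minimum effective rooting depth,0.20,0.40,uniform,0,m
X21,Maximum effective rooting depth,1.00,2.00,uniform,0,m
X22,Shape factor describing root zone expansion,10,20,uniform,1,-
X23,Maximum root water extraction in top quarter of root zone,0.030,0.060,uniform,0,m3/m3/day
X24,Maximum root water extraction in bottom quarter of root zone,0.008,0.020,uniform,0,m3/m3/day
X25,Effect of canopy cover in reducing soil evaporation in late season stage,50,70,uniform,1,%
X26,Soil surface covered by an individual seedling at 90% emergence,1.0,3.0,uniform,0,cm2
X27,Canopy size of individual plant at re-growth,1.0,3.0,uniform,0,cm2
X28,Number of plants per hectare,3000000,5000000,uniform,1,plants/ha
X29,Canopy growth coefficient (CGC): increase in fraction soil cover per day,0.04,0.12,uniform,0,1/day
X30,Maximum canopy cover (CCx) in fraction soil cover,0.70,0.98,uniform,0,fraction
X31,Water productivity normalized for ETo and CO2 (WP*),13,20,uniform,0,g/m2
X32,Water productivity during yield formation as percent of WP*,90,110,uniform,1,%
X33,Crop performance under elevated atmospheric CO2 concentration,50,100,uniform,1,%
X34,Reference harvest index (HIo),40,55,uniform,1,%
X35,Possible increase of HI due to water stress before flowering,0,10,uniform,1,%
X36,Coefficient describing positive impact on HI of restricted vegetative growth during yield formation,0,10,uniform,0,-
X37,Coefficient describing negative impact on HI of stomatal closure during yield formation,0,10,uniform,0,-
X38,Allowable maximum increase of specified HI,10,20,uniform,1,%
X39,Growing degree days from sowing to emergence,100,250,uniform,1,degC day
X40,Growing degree days from sowing to maximum rooting depth,800,1500,uniform,1,degC day
X41,Growing degree days from sowing to start senescence,1400,1900,uniform,1,degC day
X42,Growing degree days from sowing to maturity (length of crop cycle),1800,2400,uniform,1,degC day
X43,Growing degree days from sowing to flowering,1000,1400,uniform,1,degC day
X44,Length of the flowering stage,100,300,uniform,1,degC day
X45,CGC expressed per growing degree day,0.003,0.009,uniform,0,1/degC day
X46,CDC: decrease in canopy cover per growing degree day,0.002,0.010,uniform,0,1/degC day
X47,Growing degree days for building up of harvest index during yield formation,500,1100,uniform,1,degC day
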