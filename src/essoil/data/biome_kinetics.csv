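# Decomposition kinetics by biome cluster (1 tropical forest, 2 temperate
# grassland, 3 temperate deciduous forest, 4 cold coniferous forest,
# 5 boreal forest/tundra), following the cross-latitudinal pattern of
# higher temperature sensitivity of enzyme kinetics at higher latitudes
# (German et al. 2012, Glob. Change Biol.).  Stand-in values: replace with
# site-calibrated kinetics for quantitative work.  Pre-exponentials are
# chosen so all biomes have comparable rates at 20 C.
biome,v0D,EvD,K0D,EKD
1,1.6e+7,42.0,2.4e+7,26.5
2,4.1e+7,44.5,4.9e+7,28.0
3,1.0e+8,47.0,1.0e+8,30.0
4,2.6e+8,49.5,2.1e+8,32.0
5,7.0e+8,52.0,4.4e+8,34.0
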