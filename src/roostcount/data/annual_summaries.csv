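roost,stratum,2004,2005,2006,2007,2008,2009,median,iqr
1,all_parrots,1059,2356,2213,2348,3038,3032,2352,617
1,singles_pct,2.4,1.3,3.2,2.6,2.7,-,2.6,0.3
1,paired_pct,-,28.4,28.8,26.2,43.7,76.2,28.8,15.3
1,fledglings_pct,1.5,6.9,4.1,3.5,1.6,2,2.8,2.2
2,all_parrots,784,652,620,608,1802,836,718,195
2,singles_pct,1.8,7.8,12.4,2.1,7.2,-,7.2,5.7
2,paired_pct,-,67.9,60.5,67.1,77.3,84.1,67.9,10.2
2,fledglings_pct,-,6.5,5,2.1,3.2,2.1,3.2,2.9
3,all_parrots,318,1246,571,328,635,913,603,455
3,singles_pct,17.6,4.7,10,27.7,35.9,-,17.6,17.7
3,paired_pct,-,55.3,74.1,80.5,92.8,90.5,80.5,16.4
3,fledglings_pct,3,4.5,5.1,3.4,1.9,2.6,3.2,1.5
4,all_parrots,583,1030,676,1078,-,-,853,389
4,singles_pct,7,4.5,5.3,2.2,-,-,4.9,1.8
4,paired_pct,47.7,64.9,81.1,74.9,-,-,69.9,15.8
4,fledglings_pct,-,9.3,5.8,4.9,-,-,5.8,2.2
5,all_parrots,-,260,127,-,-,-,194,66
5,singles_pct,-,12.3,7.9,-,-,-,10.1,2.2
5,paired_pct,-,78.3,66.9,-,-,-,72.7,5.8
5,fledglings_pct,-,7.3,5.9,-,-,-,6.6,0.7
pooled,all_parrots,2744,5544,4207,4362,5475,4781,4571,1056
pooled,singles_pct,5.0,3.9,5.9,4.3,8.0,-,5,1.6
pooled,paired_pct,-,48.2,49.2,48.0,60.4,80.3,49.2,12.2
pooled,fledglings_pct,-,6.8,6.5,3.6,2.2,2.1,3.6,4.3
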