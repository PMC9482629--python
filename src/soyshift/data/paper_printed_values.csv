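scenario,quantity,value,unit,flag,note
ASM,gross_avoided,409,kha,,gross avoided deforestation in the Brazilian Amazon 2011-2016
ASM,net_brazil,194,kha,,net avoided deforestation within Brazil
ASM,bap_displaced,2,kha,upper_bound,cross-border spillover to Bolivia/Argentina/Paraguay printed as "<2"
ASM,row_displaced,11,kha,,deforestation increase in the rest of the world
ASM,net_global,180,kha,printed_from_unrounded,global net avoided deforestation
ASM,ghg_savings,153,kt_co2e,,avoided land-use-change GHG emissions
ASM,domestic_rate,53,pct,,within-country leakage rate
ASM,crossborder_rate,3,pct,lower_bound,cross-border leakage rate printed as "just above 3%"
ASM,annualized,82,kha_per_yr,,gross avoided per year over the 5-year window
ASM,net_amazon_cerrado,238,kha,ambiguous,text says 238 is "about 23%" of 847 but 238/847 = 28.1%; excluded from checks
GlobalZDC,gross_added_vs_asm,167,kha,,additional gross avoided deforestation over the ASM scenario
GlobalZDC,gross_avoided,576,kha,,total gross avoided (409 + 167)
GlobalZDC,net_brazil,306,kha,,net avoided deforestation within Brazil
GlobalZDC,net_cerrado,39,kha,,net avoided deforestation in the Cerrado
GlobalZDC,bap_displaced,3,kha,,spillover to Bolivia/Argentina/Paraguay
GlobalZDC,row_displaced,14,kha,,spillover to the rest of the world
GlobalZDC,net_global,288,kha,printed_from_unrounded,global net avoided deforestation
GlobalZDC,ghg_savings,220,kt_co2e,,avoided GHG emissions
GlobalZDC,domestic_rate,47,pct,,within-country leakage rate
GlobalZDC,crossborder_rate,3,pct,,combined cross-border leakage rate
GlobalZDC,gross_increase_vs_asm,40,pct,printed_from_unrounded,gross forest savings increase relative to ASM-only
EU,net_brazil,419,kha,,net avoided deforestation within Brazil
EU,net_amazon_cerrado,340,kha,,net forest savings in the Amazon plus Cerrado
EU,domestic_rate,43,pct,,within-country leakage rate
EU,ghg_savings,297,kt_co2e,,avoided GHG emissions
EU,net_global,398,kha,,global net avoided deforestation
EU,net_increase_vs_gzdc,37,pct,,increase in Brazilian forest savings over global pledges
EU,global_increase_vs_gzdc,38,pct,,increase in global net avoided deforestation over global pledges
EU,ghg_reduction_vs_gzdc,35,pct,,GHG-saving increase over the global-pledge scenario
EU,annual_net_global,80,kha_per_yr,,global net avoided deforestation per year
EU,biome_share,40,pct,,340 kha as a share of observed soy deforestation (847 kha)
China,net_brazil,429,kha,,net avoided deforestation within Brazil
China,net_global,408,kha,,global net avoided deforestation
China,ghg_savings,300,kt_co2e,,avoided GHG emissions
ref,soy_deforestation_amazon_cerrado,847,kha,,observed deforestation for soy in Amazon+Cerrado 2011-2016
ref,lucf_global,4018,mt_co2e,,global land-use-change-and-forestry emissions in the window
ref,lucf_brazil,1730,mt_co2e,,Brazil's LUCF emissions in the window
ref,horizon,5,years,,medium-run window 2011-2016
ref,ghg_share_global_asm,0.004,pct,,153 kt as a share of global LUCF emissions
ref,ghg_share_brazil_asm,0.01,pct,,153 kt as a share of Brazil's LUCF emissions
ref,ghg_share_global_gzdc,0.005,pct,,220 kt as a share of global LUCF emissions
ref,ghg_share_brazil_gzdc,0.01,pct,,220 kt as a share of Brazil's LUCF emissions
ref,ghg_share_global_eu,0.007,pct,,297 kt as a share of global LUCF emissions
ref,ghg_share_brazil_eu,0.02,pct,,297 kt as a share of Brazil's LUCF emissions
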