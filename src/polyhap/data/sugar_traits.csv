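accession,group,brix,sucrose,fiber,reducing_sugar
YZ02-588,HS,23.6,16.12,11.34,0.24
YZ14-401,HS,23.21,15.86,14.27,0.49
YZ14-405,HS,23.71,15.86,16.25,0.27
YT00-236,HS,22.25,16.26,11.35,0.34
Dezhe93-88,HS,22.44,15.54,14.07,0.34
YZ14-407,HS,22.34,15.76,15.08,0.78
YZ94-343,LS,18.9,14.85,11.28,1.27
GT12,LS,19.41,13.87,11.89,1.5
YZ14-406,LS,20.32,13.83,13.2,0.67
YZ14-403,LS,19.13,13.2,15.56,1.01
YZ14-404,LS,19.62,13.99,13.41,0.97
YZ14-402,LS,15.78,8.5,9.04,0.84
YZ14-408,LS,18.66,13.06,11.89,1.54
Badila,ANCESTRAL,20.85,15.2,10.3,0.25
Guangze bamboo cane,ANCESTRAL,18.61,12.34,14.28,
Katha,ANCESTRAL,19.69,12.13,16.92,
India1,ANCESTRAL,17.21,,27.47,
ROC22,CK,20.92,13.07,11.09,1.42
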