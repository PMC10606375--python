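group,replicate,time_h,q_ug_per_cm2,layer,amount_ug,mass_mg
ointment-ivrt,rep1,0.5,0.637581797297172,,,
ointment-ivrt,rep1,1.0,1.5864024015442235,,,
ointment-ivrt,rep1,2.0,2.5855644859341136,,,
ointment-ivrt,rep1,4.0,3.6336525404159103,,,
ointment-ivrt,rep1,6.0,5.594603597608867,,,
ointment-ivrt,rep1,8.0,8.876484964098422,,,
ointment-ivrt,rep1,24.0,16.408743344004066,,,
ointment-ivrt,rep2,0.5,0.6938277141643181,,,
ointment-ivrt,rep2,1.0,0.859768930068582,,,
ointment-ivrt,rep2,2.0,3.0727901094132624,,,
ointment-ivrt,rep2,4.0,5.655048827776775,,,
ointment-ivrt,rep2,6.0,4.92505876304345,,,
ointment-ivrt,rep2,8.0,7.469232200254464,,,
ointment-ivrt,rep2,24.0,15.094471631401492,,,
ointment-ivrt,rep3,0.5,0.5496618609527375,,,
ointment-ivrt,rep3,1.0,1.3326504209450876,,,
ointment-ivrt,rep3,2.0,2.0851934875379454,,,
ointment-ivrt,rep3,4.0,3.7387724646795775,,,
ointment-ivrt,rep3,6.0,6.843380075179007,,,
ointment-ivrt,rep3,8.0,9.628255370994243,,,
ointment-ivrt,rep3,24.0,15.587495768587148,,,
ointment-ivrt,rep4,0.5,0.6128302373864988,,,
ointment-ivrt,rep4,1.0,0.9336831317050799,,,
ointment-ivrt,rep4,2.0,2.633749631051587,,,
ointment-ivrt,rep4,4.0,6.09812136870629,,,
ointment-ivrt,rep4,6.0,6.77165826093954,,,
ointment-ivrt,rep4,8.0,7.826610546380693,,,
ointment-ivrt,rep4,24.0,12.25449742586332,,,
ointment-ivrt,rep5,0.5,0.56012965686879,,,
ointment-ivrt,rep5,1.0,0.8495675311016369,,,
ointment-ivrt,rep5,2.0,2.555273636635528,,,
ointment-ivrt,rep5,4.0,5.67567177756377,,,
ointment-ivrt,rep5,6.0,7.658008174651203,,,
ointment-ivrt,rep5,8.0,8.104410795459039,,,
ointment-ivrt,rep5,24.0,18.02522988648885,,,
ointment-ivrt,rep6,0.5,0.5297650062153837,,,
ointment-ivrt,rep6,1.0,1.2036691087913796,,,
ointment-ivrt,rep6,2.0,2.3491051277369106,,,
ointment-ivrt,rep6,4.0,4.30763592713072,,,
ointment-ivrt,rep6,6.0,4.0981607143741,,,
ointment-ivrt,rep6,8.0,8.203680001697311,,,
ointment-ivrt,rep6,24.0,17.852816600572183,,,
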