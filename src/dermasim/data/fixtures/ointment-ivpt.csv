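group,replicate,time_h,q_ug_per_cm2,layer,amount_ug,mass_mg
ointment-ivpt,rep1,12.0,2.4353217965964147,,,
ointment-ivpt,rep1,14.0,3.186093927935634,,,
ointment-ivpt,rep1,16.0,3.313521569804072,,,
ointment-ivpt,rep1,18.0,4.341963493981531,,,
ointment-ivpt,rep1,20.0,5.064957262982877,,,
ointment-ivpt,rep1,22.0,5.83267683996177,,,
ointment-ivpt,rep1,24.0,9.00507060802768,,,
ointment-ivpt,rep1,36.0,10.34629571243579,,,
ointment-ivpt,rep1,,,dermis,0.32559604330868164,76.8
ointment-ivpt,rep1,,,epidermis,3.2791874734139608,4.4848
ointment-ivpt,rep2,12.0,2.144051062270445,,,
ointment-ivpt,rep2,14.0,2.737106832167217,,,
ointment-ivpt,rep2,16.0,4.2435440807747735,,,
ointment-ivpt,rep2,18.0,4.088616390694859,,,
ointment-ivpt,rep2,20.0,4.998326843287376,,,
ointment-ivpt,rep2,22.0,6.594664005376987,,,
ointment-ivpt,rep2,24.0,7.284677217991143,,,
ointment-ivpt,rep2,36.0,9.333416245192886,,,
ointment-ivpt,rep2,,,dermis,0.3438989586483979,76.8
ointment-ivpt,rep2,,,epidermis,3.5429235130233305,4.4848
ointment-ivpt,rep3,12.0,2.935735442587471,,,
ointment-ivpt,rep3,14.0,3.054516749389299,,,
ointment-ivpt,rep3,16.0,4.189968853193743,,,
ointment-ivpt,rep3,18.0,4.568404112632761,,,
ointment-ivpt,rep3,20.0,6.541732426123302,,,
ointment-ivpt,rep3,22.0,5.4907888508691425,,,
ointment-ivpt,rep3,24.0,5.926276542526027,,,
ointment-ivpt,rep3,36.0,11.479888286245608,,,
ointment-ivpt,rep3,,,dermis,0.3202060928872303,76.8
ointment-ivpt,rep3,,,epidermis,2.6292022595198175,4.4848
ointment-ivpt,rep4,12.0,2.7558005013141034,,,
ointment-ivpt,rep4,14.0,2.9268738606272673,,,
ointment-ivpt,rep4,16.0,4.165699077773964,,,
ointment-ivpt,rep4,18.0,5.498416838569349,,,
ointment-ivpt,rep4,20.0,4.107663534705559,,,
ointment-ivpt,rep4,22.0,7.1219890211558665,,,
ointment-ivpt,rep4,24.0,7.728573672118497,,,
ointment-ivpt,rep4,36.0,10.059627287205894,,,
ointment-ivpt,rep4,,,dermis,0.313075252301305,76.8
ointment-ivpt,rep4,,,epidermis,3.301293899010683,4.4848
ointment-ivpt,rep5,12.0,2.2276657342687076,,,
ointment-ivpt,rep5,14.0,2.7396655439301023,,,
ointment-ivpt,rep5,16.0,4.1256717933550755,,,
ointment-ivpt,rep5,18.0,3.9752306852323835,,,
ointment-ivpt,rep5,20.0,5.595403054170375,,,
ointment-ivpt,rep5,22.0,7.1423599408845,,,
ointment-ivpt,rep5,24.0,5.021530272413556,,,
ointment-ivpt,rep5,36.0,11.553244550519803,,,
ointment-ivpt,rep5,,,dermis,0.5065395000501598,76.8
ointment-ivpt,rep5,,,epidermis,2.708837652812863,4.4848
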