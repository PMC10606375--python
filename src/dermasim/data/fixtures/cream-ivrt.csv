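group,replicate,time_h,q_ug_per_cm2,layer,amount_ug,mass_mg
cream-ivrt,rep1,0.5,2.022512885232726,,,
cream-ivrt,rep1,1.0,3.297180863841999,,,
cream-ivrt,rep1,2.0,9.439626752301905,,,
cream-ivrt,rep1,4.0,18.108070190749533,,,
cream-ivrt,rep1,6.0,21.952588957135422,,,
cream-ivrt,rep1,8.0,30.800896804277773,,,
cream-ivrt,rep1,24.0,78.04417276443165,,,
cream-ivrt,rep2,0.5,2.665629667606968,,,
cream-ivrt,rep2,1.0,4.963551380473918,,,
cream-ivrt,rep2,2.0,9.559287446708536,,,
cream-ivrt,rep2,4.0,14.246606729164494,,,
cream-ivrt,rep2,6.0,26.54599331947647,,,
cream-ivrt,rep2,8.0,22.802189822966508,,,
cream-ivrt,rep2,24.0,57.547156539755214,,,
cream-ivrt,rep3,0.5,2.131818539139393,,,
cream-ivrt,rep3,1.0,3.451222994412042,,,
cream-ivrt,rep3,2.0,8.486403125386742,,,
cream-ivrt,rep3,4.0,20.707215815130276,,,
cream-ivrt,rep3,6.0,21.853134697654927,,,
cream-ivrt,rep3,8.0,24.352097568699186,,,
cream-ivrt,rep3,24.0,59.65389866398312,,,
cream-ivrt,rep4,0.5,2.5846283557694325,,,
cream-ivrt,rep4,1.0,4.5969230817635145,,,
cream-ivrt,rep4,2.0,8.6238055596343,,,
cream-ivrt,rep4,4.0,13.132963956839207,,,
cream-ivrt,rep4,6.0,24.774493698616475,,,
cream-ivrt,rep4,8.0,31.34975822577448,,,
cream-ivrt,rep4,24.0,73.86310766105767,,,
cream-ivrt,rep5,0.5,2.8414702602626765,,,
cream-ivrt,rep5,1.0,4.949462416947695,,,
cream-ivrt,rep5,2.0,6.752620974767762,,,
cream-ivrt,rep5,4.0,13.081794521167879,,,
cream-ivrt,rep5,6.0,19.51724566652146,,,
cream-ivrt,rep5,8.0,30.470064060261066,,,
cream-ivrt,rep5,24.0,53.76974819103293,,,
cream-ivrt,rep6,0.5,2.766391937224207,,,
cream-ivrt,rep6,1.0,4.6317767604622135,,,
cream-ivrt,rep6,2.0,9.109657684197881,,,
cream-ivrt,rep6,4.0,18.12486155306911,,,
cream-ivrt,rep6,6.0,24.18743992714929,,,
cream-ivrt,rep6,8.0,23.625877902790986,,,
cream-ivrt,rep6,24.0,87.17233826587773,,,
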