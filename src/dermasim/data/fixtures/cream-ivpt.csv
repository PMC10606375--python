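group,replicate,time_h,q_ug_per_cm2,layer,amount_ug,mass_mg
cream-ivpt,rep1,12.0,20.336116151529307,,,
cream-ivpt,rep1,14.0,18.29252718917756,,,
cream-ivpt,rep1,16.0,29.822408173062936,,,
cream-ivpt,rep1,18.0,26.772951181721773,,,
cream-ivpt,rep1,20.0,43.36791338201084,,,
cream-ivpt,rep1,22.0,33.21372541451419,,,
cream-ivpt,rep1,24.0,42.10158065743787,,,
cream-ivpt,rep1,36.0,69.17287422350304,,,
cream-ivpt,rep1,,,dermis,1.9875820461546307,76.8
cream-ivpt,rep1,,,epidermis,21.72247479263082,4.4848
cream-ivpt,rep2,12.0,12.600955537864104,,,
cream-ivpt,rep2,14.0,25.143478576281527,,,
cream-ivpt,rep2,16.0,21.48087027349205,,,
cream-ivpt,rep2,18.0,26.346349934896907,,,
cream-ivpt,rep2,20.0,33.97447480371481,,,
cream-ivpt,rep2,22.0,46.809771338698894,,,
cream-ivpt,rep2,24.0,41.460806398585525,,,
cream-ivpt,rep2,36.0,101.8765512729511,,,
cream-ivpt,rep2,,,dermis,2.4244265647259,76.8
cream-ivpt,rep2,,,epidermis,18.430631726197443,4.4848
cream-ivpt,rep3,12.0,17.186032315631476,,,
cream-ivpt,rep3,14.0,21.20583733625338,,,
cream-ivpt,rep3,16.0,28.94774947933826,,,
cream-ivpt,rep3,18.0,31.39859558918636,,,
cream-ivpt,rep3,20.0,31.56564672219892,,,
cream-ivpt,rep3,22.0,38.592375732140894,,,
cream-ivpt,rep3,24.0,47.98775105637957,,,
cream-ivpt,rep3,36.0,95.80655063076765,,,
cream-ivpt,rep3,,,dermis,2.582034188048546,76.8
cream-ivpt,rep3,,,epidermis,13.984468704729206,4.4848
cream-ivpt,rep4,12.0,17.941442500815263,,,
cream-ivpt,rep4,14.0,23.767717451995967,,,
cream-ivpt,rep4,16.0,19.391024096155743,,,
cream-ivpt,rep4,18.0,30.765329336688524,,,
cream-ivpt,rep4,20.0,36.80663992600534,,,
cream-ivpt,rep4,22.0,54.46542965921967,,,
cream-ivpt,rep4,24.0,59.371981218215,,,
cream-ivpt,rep4,36.0,77.07588170782233,,,
cream-ivpt,rep4,,,dermis,3.0420571996343337,76.8
cream-ivpt,rep4,,,epidermis,20.476226138767384,4.4848
cream-ivpt,rep5,12.0,18.663719265320868,,,
cream-ivpt,rep5,14.0,21.911662690734016,,,
cream-ivpt,rep5,16.0,24.27870206482759,,,
cream-ivpt,rep5,18.0,32.095597681748046,,,
cream-ivpt,rep5,20.0,34.93741204761037,,,
cream-ivpt,rep5,22.0,43.95658329526514,,,
cream-ivpt,rep5,24.0,51.82128187739182,,,
cream-ivpt,rep5,36.0,73.48479787792913,,,
cream-ivpt,rep5,,,dermis,2.5768661906294743,76.8
cream-ivpt,rep5,,,epidermis,18.27291432745881,4.4848
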