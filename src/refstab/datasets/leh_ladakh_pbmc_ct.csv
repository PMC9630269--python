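gene,LAC_1,LAC_2,LAC_3,LAC_4,LAC_5,LAC_6,LAY_11,LAY_12,LAY_15,LAY_16,LAY_18,LAY_19,LAD_1,LAD_2,LAD_3,LAD_4,LAD_5,CHG_27,CHG_28,CHG_29,CHG_30,CHG_33,DHC_34,DHC_35,DHC_37,DHC_38,DHC_39,ZAP_1,ZAP_2,ZAP_3,ZAP_4,ZAP_5
GAPDH,22.166,21.865,22.08,22.295,22.525,22.065,18.984,17.341,17.458,18.306,19.202,18.548,22.631,24.527,20.735,23.579,22.868,14.35,15.877,17.404,16.321,15.238,23.103,22.565,20.412,24.128,22.619,23.198,19.785,20.695,25.664,19.687
ACTB,24.35,22.88,23.515,24.66,22.64,24.9,22.124,20.518,19.617,21.148,21.497,20.981,21.085,20.87,20.623,19.967,20.767,18.64,18.359,17.562,18.014,17.09,18.367,19.002,19.155,19.254,19.997,16.494,16.688,18.157,19.94,16.401
RPS9,22.395,20.15,19.975,19.865,20.035,20.41,22.675,21.299,21.063,22.322,23.42,22.407,19.703,20.745,19.752,22.779,24.162,19.792,19.575,19.358,19.434,19.151,19.258,19.688,18.55,19.583,20.835,21.355,21.265,21.454,19.839,21.097
EEF1A1,18.81,17.32,16.895,17.26,17.09,17.225,23.616,20.124,19.573,23.314,23.584,23.161,18.913,20.654,17.94,19.457,20.442,18.836,20.644,18.338,20.044,17.746,17.584,17.167,17.387,17.93,16.869,20.253,19.61,20.502,18.813,19.991
RPS15,19.511,19.785,19.55,19.57,19.205,19.445,33.537,29.057,30.821,30.667,33.815,33.664,34.072,31.857,33.395,34.096,35.473,34.923,30.897,34.623,33.763,30.183,30.718,33.965,31.888,34.898,30.624,34.904,36.059,36.064,33.605,34.567
RPS23,15.934,14.275,14.24,14.094,13.943,14.062,17.509,15.891,14.365,15.7,16.677,16.822,14.334,14.842,14.63,14.027,13.857,13.633,15.23,15.027,14.099,13.943,17.048,16.055,16.886,17.266,17.983,18.13,17.718,17.868,16.471,17.589
UXT,26.065,23.86,24.175,24.545,24.675,24.505,22.22,22.872,22.848,23.041,22.838,22.763,23.918,22.433,23.017,22.706,21.455,21.406,20.443,22.621,20.786,21.771,18.195,20.889,19.762,19.434,20.106,27.172,27.222,27.144,26.166,27.407
RPL4,21.56,20.055,19.665,20.145,19.605,19.75,23.867,24.407,25.646,23.709,24.405,23.866,21.676,21.309,23.167,21.676,20.553,23.87,20.81,23.095,20.015,22.071,18.228,22.323,20.84,18.681,21.816,19.203,18.761,19.211,17.547,18.887
B2M,19.355,18.195,18.715,18.565,18.745,17.735,22.913,20.86,18.109,22.436,22.954,21.809,17.632,18.578,16.685,18.105,17.75,28.316,33.046,32.082,31.783,26.7,20.174,21.401,19.244,20.421,20.867,16.34,16.059,20.486,19.799,16.074
HPRT1,30.175,28.375,27.95,28.135,28.865,29.69,24.79,24.951,24.333,25.037,25.41,25.026,25.613,26.04,24.795,25.826,25.568,25.075,25.448,24.355,24.553,24.858,21.929,22.778,22.105,22.271,22.271,22.058,25.723,26.809,24.798,25.422
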