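region,category,rank,composite,resource_acquisition,functional_performance,performance_level,learning_development,internet_application
Beijing,eastern,2,0.172,0.144,0.334,0.053,0.281,0.022
Tianjin,eastern,10,0.119,0.071,0.233,0.042,0.191,0.036
Hebei,eastern,26,0.080,0.022,0.159,0.021,0.138,0.052
Shanxi,central,16,0.111,0.032,0.220,0.012,0.208,0.083
Inner Mongolia,central,18,0.104,0.044,0.223,0.016,0.206,0.008
Liaoning,eastern,7,0.139,0.027,0.269,0.051,0.218,0.122
Jilin,central,5,0.147,0.017,0.327,0.059,0.267,0.002
Heilongjiang,central,8,0.138,0.017,0.310,0.033,0.277,0.003
Shanghai,eastern,4,0.162,0.150,0.299,0.013,0.286,0.075
Jiangsu,eastern,1,0.204,0.071,0.379,0.150,0.228,0.147
Zhejiang,eastern,2,0.172,0.080,0.316,0.059,0.257,0.154
Anhui,central,6,0.141,0.022,0.303,0.063,0.240,0.026
Fujian,eastern,12,0.115,0.053,0.244,0.022,0.223,0.003
Jiangxi,central,13,0.114,0.021,0.250,0.044,0.206,0.004
Shandong,eastern,11,0.118,0.033,0.251,0.058,0.193,0.006
Henan,central,22,0.096,0.012,0.212,0.035,0.177,0.008
Hubei,central,25,0.091,0.028,0.193,0.031,0.162,0.010
Hunan,central,29,0.075,0.016,0.164,0.017,0.146,0.012
Guangdong,eastern,23,0.094,0.056,0.184,0.055,0.129,0.016
Guangxi,eastern,27,0.079,0.011,0.173,0.013,0.160,0.019
Hainan,eastern,21,0.098,0.028,0.211,0.013,0.198,0.022
Chongqing,western,14,0.113,0.027,0.245,0.009,0.236,0.026
Sichuan,western,17,0.106,0.025,0.211,0.096,0.115,0.032
Guizhou,western,15,0.112,0.008,0.246,0.009,0.237,0.038
Yunnan,western,19,0.102,0.006,0.222,0.009,0.213,0.045
Tibet,western,24,0.093,0.010,0.196,0.005,0.191,0.059
Shaanxi,western,9,0.121,0.029,0.252,0.011,0.240,0.061
Gansu,western,20,0.100,0.004,0.213,0.016,0.197,0.056
Qinghai,western,28,0.077,0.013,0.159,0.006,0.153,0.050
Ningxia,western,30,0.059,0.021,0.115,0.006,0.109,0.044
Xinjiang,western,31,0.038,0.020,0.072,0.006,0.066,0.031
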