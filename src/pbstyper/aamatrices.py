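"""Standard empirical amino-acid replacement models.

Exchangeability matrices (symmetric, zero diagonal) and stationary
frequencies for WAG, LG, JTT and Dayhoff, in the conventional residue
order ``ARNDCQEGHILKMFPSTWYV``. Values are the published ones from the
original model papers (as distributed with PAML/RAxML/phangorn).
"""
import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

WAG_FREQS = np.array([
    0.08662790866, 0.04397200440, 0.03908940391, 0.05704510570, 0.01930780193,
    0.03672810367, 0.05805890581, 0.08325180833, 0.02443130244, 0.04846600485,
    0.08620900862, 0.06202860620, 0.01950270195, 0.03843190384, 0.04576310458,
    0.06951790695, 0.06101270610, 0.01438590144, 0.03527420353, 0.07089560709,
])
WAG_RATES = np.array([
    [0.000000, 0.551571, 0.509848, 0.738998, 1.027040, 0.908598, 1.582850, 1.416720, 0.316954, 0.193335, 0.397915, 0.906265, 0.893496, 0.210494, 1.438550, 3.370790, 2.121110, 0.113133, 0.240735, 2.006010],
    [0.551571, 0.000000, 0.635346, 0.147304, 0.528191, 3.035500, 0.439157, 0.584665, 2.137150, 0.186979, 0.497671, 5.351420, 0.683162, 0.102711, 0.679489, 1.224190, 0.554413, 1.163920, 0.381533, 0.251849],
    [0.5098480, 0.6353460, 0.0000000, 5.4294200, 0.2652560, 1.5436400, 0.9471980, 1.1255600, 3.9562900, 0.5542360, 0.1315280, 3.0120100, 0.1982210, 0.0961621, 0.1950810, 3.9742300, 2.0300600, 0.0719167, 1.0860000, 0.1962460],
    [0.7389980, 0.1473040, 5.4294200, 0.0000000, 0.0302949, 0.6167830, 6.1741600, 0.8655840, 0.9306760, 0.0394370, 0.0848047, 0.4798550, 0.1037540, 0.0467304, 0.4239840, 1.0717600, 0.3748660, 0.1297670, 0.3257110, 0.1523350],
    [1.0270400, 0.5281910, 0.2652560, 0.0302949, 0.0000000, 0.0988179, 0.0213520, 0.3066740, 0.2489720, 0.1701350, 0.3842870, 0.0740339, 0.3904820, 0.3980200, 0.1094040, 1.4076600, 0.5129840, 0.7170700, 0.5438330, 1.0021400],
    [0.9085980, 3.0355000, 1.5436400, 0.6167830, 0.0988179, 0.0000000, 5.4694700, 0.3300520, 4.2941100, 0.1139170, 0.8694890, 3.8949000, 1.5452600, 0.0999208, 0.9333720, 1.0288700, 0.8579280, 0.2157370, 0.2277100, 0.3012810],
    [1.5828500, 0.4391570, 0.9471980, 6.1741600, 0.0213520, 5.4694700, 0.0000000, 0.5677170, 0.5700250, 0.1273950, 0.1542630, 2.5844300, 0.3151240, 0.0811339, 0.6823550, 0.7049390, 0.8227650, 0.1565570, 0.1963030, 0.5887310],
    [1.4167200, 0.5846650, 1.1255600, 0.8655840, 0.3066740, 0.3300520, 0.5677170, 0.0000000, 0.2494100, 0.0304501, 0.0613037, 0.3735580, 0.1741000, 0.0499310, 0.2435700, 1.3418200, 0.2258330, 0.3369830, 0.1036040, 0.1872470],
    [0.316954, 2.137150, 3.956290, 0.930676, 0.248972, 4.294110, 0.570025, 0.249410, 0.000000, 0.138190, 0.499462, 0.890432, 0.404141, 0.679371, 0.696198, 0.740169, 0.473307, 0.262569, 3.873440, 0.118358],
    [0.1933350, 0.1869790, 0.5542360, 0.0394370, 0.1701350, 0.1139170, 0.1273950, 0.0304501, 0.1381900, 0.0000000, 3.1709700, 0.3238320, 4.2574600, 1.0594700, 0.0999288, 0.3194400, 1.4581600, 0.2124830, 0.4201700, 7.8213000],
    [0.3979150, 0.4976710, 0.1315280, 0.0848047, 0.3842870, 0.8694890, 0.1542630, 0.0613037, 0.4994620, 3.1709700, 0.0000000, 0.2575550, 4.8540200, 2.1151700, 0.4158440, 0.3447390, 0.3266220, 0.6653090, 0.3986180, 1.8003400],
    [0.9062650, 5.3514200, 3.0120100, 0.4798550, 0.0740339, 3.8949000, 2.5844300, 0.3735580, 0.8904320, 0.3238320, 0.2575550, 0.0000000, 0.9342760, 0.0888360, 0.5568960, 0.9671300, 1.3869800, 0.1375050, 0.1332640, 0.3054340],
    [0.893496, 0.683162, 0.198221, 0.103754, 0.390482, 1.545260, 0.315124, 0.174100, 0.404141, 4.257460, 4.854020, 0.934276, 0.000000, 1.190630, 0.171329, 0.493905, 1.516120, 0.515706, 0.428437, 2.058450],
    [0.2104940, 0.1027110, 0.0961621, 0.0467304, 0.3980200, 0.0999208, 0.0811339, 0.0499310, 0.6793710, 1.0594700, 2.1151700, 0.0888360, 1.1906300, 0.0000000, 0.1614440, 0.5459310, 0.1719030, 1.5296400, 6.4542800, 0.6498920],
    [1.4385500, 0.6794890, 0.1950810, 0.4239840, 0.1094040, 0.9333720, 0.6823550, 0.2435700, 0.6961980, 0.0999288, 0.4158440, 0.5568960, 0.1713290, 0.1614440, 0.0000000, 1.6132800, 0.7953840, 0.1394050, 0.2160460, 0.3148870],
    [3.370790, 1.224190, 3.974230, 1.071760, 1.407660, 1.028870, 0.704939, 1.341820, 0.740169, 0.319440, 0.344739, 0.967130, 0.493905, 0.545931, 1.613280, 0.000000, 4.378020, 0.523742, 0.786993, 0.232739],
    [2.121110, 0.554413, 2.030060, 0.374866, 0.512984, 0.857928, 0.822765, 0.225833, 0.473307, 1.458160, 0.326622, 1.386980, 1.516120, 0.171903, 0.795384, 4.378020, 0.000000, 0.110864, 0.291148, 1.388230],
    [0.1131330, 1.1639200, 0.0719167, 0.1297670, 0.7170700, 0.2157370, 0.1565570, 0.3369830, 0.2625690, 0.2124830, 0.6653090, 0.1375050, 0.5157060, 1.5296400, 0.1394050, 0.5237420, 0.1108640, 0.0000000, 2.4853900, 0.3653690],
    [0.240735, 0.381533, 1.086000, 0.325711, 0.543833, 0.227710, 0.196303, 0.103604, 3.873440, 0.420170, 0.398618, 0.133264, 0.428437, 6.454280, 0.216046, 0.786993, 0.291148, 2.485390, 0.000000, 0.314730],
    [2.006010, 0.251849, 0.196246, 0.152335, 1.002140, 0.301281, 0.588731, 0.187247, 0.118358, 7.821300, 1.800340, 0.305434, 2.058450, 0.649892, 0.314887, 0.232739, 1.388230, 0.365369, 0.314730, 0.000000],
])

LG_FREQS = np.array([
    0.07906592093, 0.05594094406, 0.04197695802, 0.05305194695, 0.01293698706,
    0.04076695923, 0.07158592841, 0.05733694266, 0.02235497765, 0.06215693784,
    0.09908090092, 0.06459993540, 0.02295097705, 0.04230195770, 0.04403995596,
    0.06119693880, 0.05328694671, 0.01206598793, 0.03415496585, 0.06914693085,
])
LG_RATES = np.array([
    [0.000000, 0.425093, 0.276818, 0.395144, 2.489084, 0.969894, 1.038545, 2.066040, 0.358858, 0.149830, 0.395337, 0.536518, 1.124035, 0.253701, 1.177651, 4.727182, 2.139501, 0.180717, 0.218959, 2.547870],
    [0.425093, 0.000000, 0.751878, 0.123954, 0.534551, 2.807908, 0.363970, 0.390192, 2.426601, 0.126991, 0.301848, 6.326067, 0.484133, 0.052722, 0.332533, 0.858151, 0.578987, 0.593607, 0.314440, 0.170887],
    [0.276818, 0.751878, 0.000000, 5.076149, 0.528768, 1.695752, 0.541712, 1.437645, 4.509238, 0.191503, 0.068427, 2.145078, 0.371004, 0.089525, 0.161787, 4.008358, 2.000679, 0.045376, 0.612025, 0.083688],
    [0.395144, 0.123954, 5.076149, 0.000000, 0.062556, 0.523386, 5.243870, 0.844926, 0.927114, 0.010690, 0.015076, 0.282959, 0.025548, 0.017416, 0.394456, 1.240275, 0.425860, 0.029890, 0.135107, 0.037967],
    [2.489084, 0.534551, 0.528768, 0.062556, 0.000000, 0.084808, 0.003499, 0.569265, 0.640543, 0.320627, 0.594007, 0.013266, 0.893680, 1.105251, 0.075382, 2.784478, 1.143480, 0.670128, 1.165532, 1.959291],
    [0.969894, 2.807908, 1.695752, 0.523386, 0.084808, 0.000000, 4.128591, 0.267959, 4.813505, 0.072854, 0.582457, 3.234294, 1.672569, 0.035855, 0.624294, 1.223828, 1.080136, 0.236199, 0.257336, 0.210332],
    [1.038545, 0.363970, 0.541712, 5.243870, 0.003499, 4.128591, 0.000000, 0.348847, 0.423881, 0.044265, 0.069673, 1.807177, 0.173735, 0.018811, 0.419409, 0.611973, 0.604545, 0.077852, 0.120037, 0.245034],
    [2.066040, 0.390192, 1.437645, 0.844926, 0.569265, 0.267959, 0.348847, 0.000000, 0.311484, 0.008705, 0.044261, 0.296636, 0.139538, 0.089586, 0.196961, 1.739990, 0.129836, 0.268491, 0.054679, 0.076701],
    [0.358858, 2.426601, 4.509238, 0.927114, 0.640543, 4.813505, 0.423881, 0.311484, 0.000000, 0.108882, 0.366317, 0.697264, 0.442472, 0.682139, 0.508851, 0.990012, 0.584262, 0.597054, 5.306834, 0.119013],
    [0.149830, 0.126991, 0.191503, 0.010690, 0.320627, 0.072854, 0.044265, 0.008705, 0.108882, 0.000000, 4.145067, 0.159069, 4.273607, 1.112727, 0.078281, 0.064105, 1.033739, 0.111660, 0.232523, 10.649107],
    [0.395337, 0.301848, 0.068427, 0.015076, 0.594007, 0.582457, 0.069673, 0.044261, 0.366317, 4.145067, 0.000000, 0.137500, 6.312358, 2.592692, 0.249060, 0.182287, 0.302936, 0.619632, 0.299648, 1.702745],
    [0.536518, 6.326067, 2.145078, 0.282959, 0.013266, 3.234294, 1.807177, 0.296636, 0.697264, 0.159069, 0.137500, 0.000000, 0.656604, 0.023918, 0.390322, 0.748683, 1.136863, 0.049906, 0.131932, 0.185202],
    [1.124035, 0.484133, 0.371004, 0.025548, 0.893680, 1.672569, 0.173735, 0.139538, 0.442472, 4.273607, 6.312358, 0.656604, 0.000000, 1.798853, 0.099849, 0.346960, 2.020366, 0.696175, 0.481306, 1.898718],
    [0.253701, 0.052722, 0.089525, 0.017416, 1.105251, 0.035855, 0.018811, 0.089586, 0.682139, 1.112727, 2.592692, 0.023918, 1.798853, 0.000000, 0.094464, 0.361819, 0.165001, 2.457121, 7.803902, 0.654683],
    [1.177651, 0.332533, 0.161787, 0.394456, 0.075382, 0.624294, 0.419409, 0.196961, 0.508851, 0.078281, 0.249060, 0.390322, 0.099849, 0.094464, 0.000000, 1.338132, 0.571468, 0.095131, 0.089613, 0.296501],
    [4.727182, 0.858151, 4.008358, 1.240275, 2.784478, 1.223828, 0.611973, 1.739990, 0.990012, 0.064105, 0.182287, 0.748683, 0.346960, 0.361819, 1.338132, 0.000000, 6.472279, 0.248862, 0.400547, 0.098369],
    [2.139501, 0.578987, 2.000679, 0.425860, 1.143480, 1.080136, 0.604545, 0.129836, 0.584262, 1.033739, 0.302936, 1.136863, 2.020366, 0.165001, 0.571468, 6.472279, 0.000000, 0.140825, 0.245841, 2.188158],
    [0.180717, 0.593607, 0.045376, 0.029890, 0.670128, 0.236199, 0.077852, 0.268491, 0.597054, 0.111660, 0.619632, 0.049906, 0.696175, 2.457121, 0.095131, 0.248862, 0.140825, 0.000000, 3.151815, 0.189510],
    [0.218959, 0.314440, 0.612025, 0.135107, 1.165532, 0.257336, 0.120037, 0.054679, 5.306834, 0.232523, 0.299648, 0.131932, 0.481306, 7.803902, 0.089613, 0.400547, 0.245841, 3.151815, 0.000000, 0.249313],
    [2.547870, 0.170887, 0.083688, 0.037967, 1.959291, 0.210332, 0.245034, 0.076701, 0.119013, 10.649107, 1.702745, 0.185202, 1.898718, 0.654683, 0.296501, 0.098369, 2.188158, 0.189510, 0.249313, 0.000000],
])

JTT_FREQS = np.array([
    0.07674792325, 0.05169094831, 0.04264495736, 0.05154394846, 0.01980298020,
    0.04075195925, 0.06182993817, 0.07315192685, 0.02294397706, 0.05376094624,
    0.09190390810, 0.05867594132, 0.02382597617, 0.04012595987, 0.05090094910,
    0.06876493124, 0.05856494144, 0.01426098574, 0.03210196790, 0.06600493400,
])
JTT_RATES = np.array([
    [0, 58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9, 11, 298],
    [58, 0, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64, 126, 20, 17],
    [54, 45, 0, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232, 8, 70, 16],
    [81, 16, 528, 0, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46, 31],
    [56, 113, 34, 10, 0, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62],
    [57, 310, 86, 49, 9, 0, 323, 26, 597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20],
    [105, 29, 58, 767, 5, 323, 0, 119, 26, 12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45],
    [179, 137, 81, 130, 59, 26, 119, 0, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47],
    [27, 328, 391, 112, 69, 597, 26, 23, 0, 16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11],
    [36, 22, 47, 11, 17, 9, 12, 6, 16, 0, 229, 21, 479, 89, 10, 40, 245, 9, 32, 961],
    [30, 38, 12, 7, 23, 72, 9, 6, 56, 229, 0, 14, 388, 248, 102, 59, 25, 52, 24, 180],
    [35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14, 0, 65, 4, 21, 47, 103, 10, 8, 14],
    [54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65, 0, 43, 16, 29, 226, 24, 18, 323],
    [15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43, 0, 17, 92, 12, 53, 536, 62],
    [194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17, 0, 285, 118, 6, 10, 23],
    [378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285, 0, 477, 35, 63, 38],
    [475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477, 0, 12, 21, 112],
    [9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 12, 0, 71, 25],
    [11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 21, 71, 0, 16],
    [298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16, 0],
])

Dayhoff_FREQS = np.array([
    0.08712691287, 0.04090395910, 0.04043195957, 0.04687195313, 0.03347396653,
    0.03825496175, 0.04952995047, 0.08861191139, 0.03361796638, 0.03688596311,
    0.08535691464, 0.08048191952, 0.01475298525, 0.03977196023, 0.05067994932,
    0.06957693042, 0.05854194146, 0.01049398951, 0.02991597008, 0.06471793528,
])
Dayhoff_RATES = np.array([
    [0, 27, 98, 120, 36, 89, 198, 240, 23, 65, 41, 26, 72, 18, 250, 409, 371, 0, 24, 208],
    [27, 0, 32, 0, 23, 246, 1, 9, 240, 64, 15, 464, 90, 14, 103, 154, 26, 201, 8, 24],
    [98, 32, 0, 905, 0, 103, 148, 139, 535, 77, 34, 318, 1, 14, 42, 495, 229, 23, 95, 15],
    [120, 0, 905, 0, 0, 134, 1153, 125, 86, 24, 0, 71, 0, 0, 13, 95, 66, 0, 0, 18],
    [36, 23, 0, 0, 0, 0, 0, 11, 28, 44, 0, 0, 0, 0, 19, 161, 16, 0, 96, 49],
    [89, 246, 103, 134, 0, 0, 716, 28, 606, 18, 73, 153, 114, 0, 153, 56, 53, 0, 0, 35],
    [198, 1, 148, 1153, 0, 716, 0, 81, 43, 61, 11, 83, 30, 0, 51, 79, 34, 0, 22, 37],
    [240, 9, 139, 125, 11, 28, 81, 0, 10, 0, 7, 27, 17, 15, 34, 234, 30, 0, 0, 54],
    [23, 240, 535, 86, 28, 606, 43, 10, 0, 7, 44, 26, 0, 48, 94, 35, 22, 27, 127, 44],
    [65, 64, 77, 24, 44, 18, 61, 0, 7, 0, 257, 46, 336, 196, 12, 24, 192, 0, 37, 889],
    [41, 15, 34, 0, 0, 73, 11, 7, 44, 257, 0, 18, 527, 157, 32, 17, 33, 46, 28, 175],
    [26, 464, 318, 71, 0, 153, 83, 27, 26, 46, 18, 0, 243, 0, 33, 96, 136, 0, 13, 10],
    [72, 90, 1, 0, 0, 114, 30, 17, 0, 336, 527, 243, 0, 92, 17, 62, 104, 0, 0, 258],
    [18, 14, 14, 0, 0, 0, 0, 15, 48, 196, 157, 0, 92, 0, 11, 46, 13, 76, 698, 12],
    [250, 103, 42, 13, 19, 153, 51, 34, 94, 12, 32, 33, 17, 11, 0, 245, 78, 0, 0, 48],
    [409, 154, 495, 95, 161, 56, 79, 234, 35, 24, 17, 96, 62, 46, 245, 0, 550, 75, 34, 30],
    [371, 26, 229, 66, 16, 53, 34, 30, 22, 192, 33, 136, 104, 13, 78, 550, 0, 0, 42, 157],
    [0, 201, 23, 0, 0, 0, 0, 0, 27, 0, 46, 0, 0, 76, 0, 75, 0, 0, 61, 0],
    [24, 8, 95, 0, 96, 0, 22, 0, 127, 37, 28, 13, 0, 698, 0, 34, 42, 61, 0, 28],
    [208, 24, 15, 18, 49, 35, 37, 54, 44, 889, 175, 10, 258, 12, 48, 30, 157, 0, 28, 0],
])

EMPIRICAL_MODELS = {
    "WAG": (WAG_RATES, WAG_FREQS),
    "LG": (LG_RATES, LG_FREQS),
    "JTT": (JTT_RATES, JTT_FREQS),
    "Dayhoff": (Dayhoff_RATES, Dayhoff_FREQS),
}
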