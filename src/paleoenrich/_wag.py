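"""Published WAG amino-acid replacement model constants.

Symmetric exchangeabilities and stationary frequencies of the WAG empirical
model (Whelan & Goldman 2001), stored in alphabetical one-letter amino-acid
order (A C D E F G H I K L M N P Q R S T V W Y).  The exchangeability matrix
carries an arbitrary overall scale; the rate matrix built from it is
renormalized to one expected substitution per site per unit time.
"""

import numpy as np

WAG_FREQUENCIES = np.array([
    0.08662790866,
    0.01930780193,
    0.0570451057,
    0.05805890581,
    0.03843190384,
    0.08325180833,
    0.02443130244,
    0.04846600485,
    0.0620286062,
    0.08620900862,
    0.01950270195,
    0.03908940391,
    0.04576310458,
    0.03672810367,
    0.0439720044,
    0.06951790695,
    0.0610127061,
    0.07089560709,
    0.01438590144,
    0.03527420353,
])

WAG_EXCHANGEABILITIES = np.array([
    [0, 1.02704, 0.738998, 1.58285, 0.210494, 1.41672, 0.316954, 0.193335, 0.906265, 0.397915, 0.893496, 0.509848, 1.43855, 0.908598, 0.551571, 3.37079, 2.12111, 2.00601, 0.113133, 0.240735],
    [1.02704, 0, 0.0302949, 0.021352, 0.39802, 0.306674, 0.248972, 0.170135, 0.0740339, 0.384287, 0.390482, 0.265256, 0.109404, 0.0988179, 0.528191, 1.40766, 0.512984, 1.00214, 0.71707, 0.543833],
    [0.738998, 0.0302949, 0, 6.17416, 0.0467304, 0.865584, 0.930676, 0.039437, 0.479855, 0.0848047, 0.103754, 5.42942, 0.423984, 0.616783, 0.147304, 1.07176, 0.374866, 0.152335, 0.129767, 0.325711],
    [1.58285, 0.021352, 6.17416, 0, 0.0811339, 0.567717, 0.570025, 0.127395, 2.58443, 0.154263, 0.315124, 0.947198, 0.682355, 5.46947, 0.439157, 0.704939, 0.822765, 0.588731, 0.156557, 0.196303],
    [0.210494, 0.39802, 0.0467304, 0.0811339, 0, 0.049931, 0.679371, 1.05947, 0.088836, 2.11517, 1.19063, 0.0961621, 0.161444, 0.0999208, 0.102711, 0.545931, 0.171903, 0.649892, 1.52964, 6.45428],
    [1.41672, 0.306674, 0.865584, 0.567717, 0.049931, 0, 0.24941, 0.0304501, 0.373558, 0.0613037, 0.1741, 1.12556, 0.24357, 0.330052, 0.584665, 1.34182, 0.225833, 0.187247, 0.336983, 0.103604],
    [0.316954, 0.248972, 0.930676, 0.570025, 0.679371, 0.24941, 0, 0.13819, 0.890432, 0.499462, 0.404141, 3.95629, 0.696198, 4.29411, 2.13715, 0.740169, 0.473307, 0.118358, 0.262569, 3.87344],
    [0.193335, 0.170135, 0.039437, 0.127395, 1.05947, 0.0304501, 0.13819, 0, 0.323832, 3.17097, 4.25746, 0.554236, 0.0999288, 0.113917, 0.186979, 0.31944, 1.45816, 7.8213, 0.212483, 0.42017],
    [0.906265, 0.0740339, 0.479855, 2.58443, 0.088836, 0.373558, 0.890432, 0.323832, 0, 0.257555, 0.934276, 3.01201, 0.556896, 3.8949, 5.35142, 0.96713, 1.38698, 0.305434, 0.137505, 0.133264],
    [0.397915, 0.384287, 0.0848047, 0.154263, 2.11517, 0.0613037, 0.499462, 3.17097, 0.257555, 0, 4.85402, 0.131528, 0.415844, 0.869489, 0.497671, 0.344739, 0.326622, 1.80034, 0.665309, 0.398618],
    [0.893496, 0.390482, 0.103754, 0.315124, 1.19063, 0.1741, 0.404141, 4.25746, 0.934276, 4.85402, 0, 0.198221, 0.171329, 1.54526, 0.683162, 0.493905, 1.51612, 2.05845, 0.515706, 0.428437],
    [0.509848, 0.265256, 5.42942, 0.947198, 0.0961621, 1.12556, 3.95629, 0.554236, 3.01201, 0.131528, 0.198221, 0, 0.195081, 1.54364, 0.635346, 3.97423, 2.03006, 0.196246, 0.0719167, 1.086],
    [1.43855, 0.109404, 0.423984, 0.682355, 0.161444, 0.24357, 0.696198, 0.0999288, 0.556896, 0.415844, 0.171329, 0.195081, 0, 0.933372, 0.679489, 1.61328, 0.795384, 0.314887, 0.139405, 0.216046],
    [0.908598, 0.0988179, 0.616783, 5.46947, 0.0999208, 0.330052, 4.29411, 0.113917, 3.8949, 0.869489, 1.54526, 1.54364, 0.933372, 0, 3.0355, 1.02887, 0.857928, 0.301281, 0.215737, 0.22771],
    [0.551571, 0.528191, 0.147304, 0.439157, 0.102711, 0.584665, 2.13715, 0.186979, 5.35142, 0.497671, 0.683162, 0.635346, 0.679489, 3.0355, 0, 1.22419, 0.554413, 0.251849, 1.16392, 0.381533],
    [3.37079, 1.40766, 1.07176, 0.704939, 0.545931, 1.34182, 0.740169, 0.31944, 0.96713, 0.344739, 0.493905, 3.97423, 1.61328, 1.02887, 1.22419, 0, 4.37802, 0.232739, 0.523742, 0.786993],
    [2.12111, 0.512984, 0.374866, 0.822765, 0.171903, 0.225833, 0.473307, 1.45816, 1.38698, 0.326622, 1.51612, 2.03006, 0.795384, 0.857928, 0.554413, 4.37802, 0, 1.38823, 0.110864, 0.291148],
    [2.00601, 1.00214, 0.152335, 0.588731, 0.649892, 0.187247, 0.118358, 7.8213, 0.305434, 1.80034, 2.05845, 0.196246, 0.314887, 0.301281, 0.251849, 0.232739, 1.38823, 0, 0.365369, 0.31473],
    [0.113133, 0.71707, 0.129767, 0.156557, 1.52964, 0.336983, 0.262569, 0.212483, 0.137505, 0.665309, 0.515706, 0.0719167, 0.139405, 0.215737, 1.16392, 0.523742, 0.110864, 0.365369, 0, 2.48539],
    [0.240735, 0.543833, 0.325711, 0.196303, 6.45428, 0.103604, 3.87344, 0.42017, 0.133264, 0.398618, 0.428437, 1.086, 0.216046, 0.22771, 0.381533, 0.786993, 0.291148, 0.31473, 2.48539, 0],
])
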