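"""Exact-derivative kernels for the stance collocation NLP.

Auto-generated by ``scripts/generate_kernels.py``; do not edit by hand.

Node variables (normalized units, M = g = L = 1): x, y, vx, vy are CoM
position/velocity relative to the stance foot; q, q1, q2 are the actuator
displacement from its nominal length and its first two time derivatives;
u is the actuator jerk (the control). Parameters: k spring stiffness,
c damping coefficient, eps force-rate cost coefficient, etp/etn signed
positive/negative work efficiencies, wd damper-switch smoothing width
(velocity units), wr power-rectification smoothing width (power units).

Functions are vectorized over collocation nodes: node variables may be
numpy arrays of equal shape. ``hess_*`` return the upper triangle of the
8x8 node Hessian row-major; ``grad_phi``/``hess_phi`` differentiate the
multiplier-weighted dynamics w0*f0 + ... + w6*f6.
"""
import numpy as np

def dyn(x, y, vx, vy, q, q1, q2, u, k, c, eps, etp, etn, wd, wr):
    x0 = x**2
    x1 = x0 + y**2
    x2 = np.sqrt(x1)
    x3 = 1/x2
    x4 = q - x2 + 1
    x5 = k*x4
    x6 = vx*x + vy*y
    x7 = q1 - x3*x6
    x8 = (1/2)*x7
    x9 = 1/wd
    x10 = np.tanh(x8*x9)
    x11 = c*(x10 + 1)
    x12 = x11*x8 + x5
    x13 = x11*x7
    x14 = x13 + 2*x5
    x15 = x14*x3
    x16 = x15*y
    x17 = k*x7
    x18 = 2*q2 - x3*(2*vx**2 + 2*vy**2 + x0*x15 + y*(x16 - 2) - 2*x6**2/x1)
    x19 = x11*x18
    x20 = x13*x18*x9*(x10 - 1)
    x21 = q1*x14
    x22 = 2*np.sqrt((1/4)*q1**2*x14**2 + wr**2)
    return [vx,
            vy,
            x*x12*x3,
            (1/2)*x16 - 1,
            q1,
            q2,
            u,
            x12,
            x17 + (1/4)*x19 - 1/8*x20,
            x4,
            x7,
            x2,
            (1/64)*eps*(8*x17 + 2*x19 - x20)**2 + (1/4)*(x21 + x22)/etp + (1/4)*(x21 - x22)/etn]


def jac_dyn(x, y, vx, vy, q, q1, q2, u, k, c, eps, etp, etn, wd, wr):
    x0 = x**2
    x1 = y**2
    x2 = x0 + x1
    x3 = np.sqrt(x2)
    x4 = 1/x3
    x5 = vx*x + vy*y
    x6 = q1 - x4*x5
    x7 = 1/wd
    x8 = x6*x7
    x9 = np.tanh((1/2)*x8)
    x10 = c*(x9 + 1)
    x11 = 2*k*(q - x3 + 1) + x10*x6
    x12 = -2*x11*x4
    x13 = 2*x11/x2**(3/2)
    x14 = 4*k
    x15 = 1/x2
    x16 = x*x15
    x17 = vx - x16*x5
    x18 = 2*x10
    x19 = x9**2 - 1
    x20 = x19*x8
    x21 = -c*x17*x20 + x*x14 + x17*x18
    x22 = x15*y
    x23 = vy - x22*x5
    x24 = -c*x19*x23*x6*x7 + x14*y + x18*x23
    x25 = (1/4)*x
    x26 = c*(-x20 + 2*x9 + 2)
    x27 = (1/4)*x15*x26
    x28 = (1/4)*y
    x29 = -x16*x26*x28
    x30 = k*x4
    x31 = x26*x4
    return [0,
            0,
            1,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            1,
            0,
            0,
            0,
            0,
            -1/4*x0*x13 - 1/4*x12 - 1/4*x16*x21,
            x25*(-x13*y - x15*x24),
            -x0*x27,
            x29,
            x*x30,
            x25*x31,
            0,
            0,
            x28*(-x*x13 - x15*x21),
            -1/4*x1*x13 - 1/4*x12 - 1/4*x22*x24,
            x29,
            -x1*x27,
            x30*y,
            x28*x31,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            1,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            1,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            1]


def grad_ell(x, y, vx, vy, q, q1, q2, u, k, c, eps, etp, etn, wd, wr):
    x0 = 4*k
    x1 = x*x0
    x2 = vx*x + vy*y
    x3 = x**2
    x4 = y**2
    x5 = x3 + x4
    x6 = 1/x5
    x7 = x2*x6
    x8 = x*x7
    x9 = vx - x8
    x10 = np.sqrt(x5)
    x11 = 1/x10
    x12 = q1 - x11*x2
    x13 = 1/wd
    x14 = x12*x13
    x15 = (1/2)*x14
    x16 = np.tanh(x15)
    x17 = x16 + 1
    x18 = c*x17
    x19 = 2*x18
    x20 = x16**2 - 1
    x21 = -c*x12*x13*x20*x9 + x1 + x19*x9
    x22 = -x21
    x23 = k*(q - x10 + 1)
    x24 = x12*x18
    x25 = 2*x23 + x24
    x26 = q1*x25/np.sqrt((1/4)*q1**2*x25**2 + wr**2)
    x27 = x26 - 2
    x28 = 4/etn
    x29 = q1*x27*x28
    x30 = x26 + 2
    x31 = 1/etp
    x32 = 4*x31
    x33 = x30*x32
    x34 = q1*x33
    x35 = 16*k
    x36 = x2**2
    x37 = 2*x6
    x38 = x11*x25
    x39 = x38*y
    x40 = 2*vx**2 + 2*vy**2 + x3*x38 - x36*x37 + y*(x39 - 2)
    x41 = 2*q2 - x11*x40
    x42 = x20*x41
    x43 = c*x13
    x44 = 2*x43
    x45 = x42*x44
    x46 = x16 - 1
    x47 = x19*x41
    x48 = x13*x47
    x49 = x46*x48
    x50 = wd**(-2)
    x51 = x42*x50
    x52 = c*x12
    x53 = x46*x51*x52
    x54 = x24*x51
    x55 = 8*x36/x5**2
    x56 = x**3
    x57 = x25/x5**(3/2)
    x58 = 2*x57
    x59 = x3*x6
    x60 = x37*x40
    x61 = 2*x
    x62 = -x9
    x63 = -x20
    x64 = x14*x63
    x65 = 8*vx*x7 - 4*x*x38 - x*x55 + x*x60 - x22*x59 + x4*(x57*x61 - x6*(c*x62*x64 - x1 + x19*x62)) + x56*x58
    x66 = x14*x46
    x67 = x18*x66
    x68 = k*x12
    x69 = x18*x41
    x70 = x66*x69
    x71 = eps*(x47 + 8*x68 - x70)
    x72 = (1/64)*x11
    x73 = x7*y
    x74 = vy - x73
    x75 = -c*x12*x13*x20*x74 + x0*y + x19*x74
    x76 = -x75
    x77 = 8*vy*x7 + x3*x58*y - 2*x39 - x55*y - x59*x76 + x60*y - y*(2*x38 - x4*x58 + x6*x76*y) + 4
    x78 = 2*x16 + 2
    x79 = x64 + x78
    x80 = c*q1
    x81 = x79*x80
    x82 = x*x81
    x83 = -x27*x28
    x84 = x41*x63
    x85 = c*x79
    x86 = x6*x85
    x87 = 8*vx - x*x4*x86 - x56*x86 - 8*x8
    x88 = -x46
    x89 = x*x88
    x90 = x50*x84
    x91 = x14*x88
    x92 = x18*x91
    x93 = x81*y
    x94 = x84*y
    x95 = 8*vy - x59*x85*y - 8*x73 - x86*y**3
    x96 = x50*x94
    x97 = -x14*x20 + x78
    x98 = x80*x97
    x99 = x26*(4*x23 + 2*x24 + x98)
    x100 = 8*x23 + 4*x24 + 2*x98
    x101 = c**2*x17*x97
    return [-x72*(x21*x34 + x22*x29 + x71*(-x19*x65 + x35*x9 - x45*x9 - x49*x9 + x53*x9 + x54*x9 + x65*x67)),
            -x72*(x29*x76 + x34*x75 + x71*(-x19*x77 + x35*x74 - x45*x74 - x49*x74 + x53*x74 + x54*x74 + x67*x77)),
            -x72*(x33*x82 + x71*(-x*x24*x90 + x*x35 + x19*x87 + x43*x61*x84 + x48*x89 + x52*x89*x90 + x87*x92) + x82*x83),
            -x72*(x33*x93 + x71*(x19*x95 - x24*x96 + x35*y + x44*x94 + x48*x88*y + x52*x88*x96 + x92*x95) + x83*x93),
            (1/16)*k*(4*q1*x30*x31 - x18*x71*(x91 + 2) - x29),
            (1/64)*x28*(x100 - x99) + (1/64)*x32*(x100 + x99) + (1/64)*x71*(x101*x66 - 2*x101 + x35 - x45 - x49 + x53 + x54),
            eps*x18*(-x15*x46 + 1)*(x68 + (1/4)*x69 - 1/8*x70),
            0]


def hess_ell(x, y, vx, vy, q, q1, q2, u, k, c, eps, etp, etn, wd, wr):
    x0 = x**2
    x1 = y**2
    x2 = x0 + x1
    x3 = np.sqrt(x2)
    x4 = 1/x3
    x5 = k*x4
    x6 = 64*x5
    x7 = -x6
    x8 = 64*k
    x9 = x2**(-3/2)
    x10 = x0*x9
    x11 = x10*x8
    x12 = 1/wd
    x13 = vx*x
    x14 = vy*y
    x15 = x13 + x14
    x16 = q1 - x15*x4
    x17 = x12*x16
    x18 = (1/2)*x17
    x19 = np.tanh(x18)
    x20 = x19 + 1
    x21 = c*x20
    x22 = 32*x21
    x23 = 1/x2
    x24 = x0*x23
    x25 = 3*x15
    x26 = 3*x13 + x14 - x24*x25
    x27 = x26*x9
    x28 = x22*x27
    x29 = x15*x23
    x30 = x*x29
    x31 = vx - x30
    x32 = x31**2
    x33 = 32*x23
    x34 = x19**2
    x35 = x34 - 1
    x36 = x12*x35
    x37 = c*x36
    x38 = x33*x37
    x39 = x32*x38
    x40 = x17*x35
    x41 = 16*x40
    x42 = c*x41
    x43 = x27*x42
    x44 = wd**(-2)
    x45 = x16*x44
    x46 = x35*x45
    x47 = x19*x23
    x48 = x46*x47
    x49 = c*x32
    x50 = x48*x49
    x51 = 16*x50
    x52 = wr**2
    x53 = q1**2
    x54 = k*(q - x3 + 1)
    x55 = x16*x21
    x56 = 2*x54 + x55
    x57 = x56**2
    x58 = x53*x57
    x59 = x52 + (1/4)*x58
    x60 = 1/np.sqrt(x59)
    x61 = 4*x60
    x62 = q1*x61
    x63 = 4*k
    x64 = x*x63
    x65 = 2*x21
    x66 = x31*x65
    x67 = c*x40
    x68 = -x31*x67 + x64 + x66
    x69 = x23*x68**2
    x70 = -4*x5
    x71 = 2*x23
    x72 = x32*x71
    x73 = x10*x63 + x27*x65 - x27*x67 - x37*x72 + x50 + x70
    x74 = q1*x56
    x75 = x60*x74
    x76 = 8*x75
    x77 = x59**(-3/2)
    x78 = q1**3*x57*x77
    x79 = x62*x69 - x69*x78 + x73*x76
    x80 = 1/etp
    x81 = q1*x80
    x82 = 1/etn
    x83 = q1*x82
    x84 = 16*k
    x85 = vx**2
    x86 = vy**2
    x87 = x15**2
    x88 = x4*x56
    x89 = x88*y
    x90 = x0*x88 - x71*x87 + 2*x85 + 2*x86 + y*(x89 - 2)
    x91 = 2*q2 - x4*x90
    x92 = 2*x35
    x93 = x12*x92
    x94 = x91*x93
    x95 = c*x94
    x96 = x19 - 1
    x97 = x12*x96
    x98 = x91*x97
    x99 = x45*x91
    x100 = x35*x99
    x101 = c*x96
    x102 = x100*x101
    x103 = x44*x91
    x104 = x103*x35
    x105 = x104*x55
    x106 = x71*x90
    x107 = x*x106
    x108 = x56*x9
    x109 = 2*x108
    x110 = x*x109
    x111 = x23*x68
    x112 = x2**(-2)
    x113 = 8*x112*x87
    x114 = 4*x88
    x115 = x**3
    x116 = 8*vx
    x117 = -x*x113 - x*x114 + x0*x111 + x109*x115 + x116*x29
    x118 = x1*(x110 + x111) + x117
    x119 = x107 + x118
    x120 = x17*x96
    x121 = x120*x21
    x122 = x102*x31 + x105*x31 + x119*x121 - x119*x65 + x31*x84 - x31*x95 - x66*x98
    x123 = eps*x23
    x124 = x84*x9
    x125 = x35**2
    x126 = x91/wd**3
    x127 = x126*x16
    x128 = x125*x127
    x129 = x128*x23
    x130 = 2*x19
    x131 = x104*x23
    x132 = x130*x131
    x133 = x104*x72
    x134 = x65*x91
    x135 = x134*x97
    x136 = x32*x47
    x137 = x127*x35
    x138 = x101*x137
    x139 = x35*x55
    x140 = x126*x139
    x141 = x31*x36
    x142 = x141*x71
    x143 = c*x142
    x144 = x119*x31
    x145 = x71*x97
    x146 = x145*x21
    x147 = x119*x23
    x148 = x31*x46
    x149 = x101*x148
    x150 = x139*x44
    x151 = x150*x23
    x152 = 6*x0
    x153 = x56/x2**(5/2)
    x154 = x152*x153
    x155 = x112*x68
    x156 = 2*x155
    x157 = x4*x73
    x158 = 8*x23
    x159 = 32*x87/x2**3
    x160 = 4*x
    x161 = x*x71
    x162 = x112*x90
    x163 = x**4
    x164 = 6*x153
    x165 = x112*x15
    x166 = 32*x165
    x167 = -x106 + x113 + x114
    x168 = -10*x0*x108 + x0*x157 - x0*x159 + x1*(x*x156 - x109 + x154 + x157) - x111*x160 + x115*x156 + x118*x161 + x13*x166 + x152*x162 - x158*x85 + x163*x164 + x167
    x169 = x4*x65
    x170 = x21*x4
    x171 = x120*x170
    x172 = 8*k*x16 - x121*x91 + x134
    x173 = eps*x172
    x174 = 2*x173
    x175 = x9*y
    x176 = vx*y
    x177 = vy*x
    x178 = x9*(x176 + x177 - 3*x30*y)
    x179 = vy - x29*y
    x180 = x148*x47
    x181 = c*x179
    x182 = -x143*x179 + x175*x64 + x178*x65 - x178*x67 + x180*x181
    x183 = x182*x76
    x184 = x179*x65
    x185 = -x179*x67 + x184 + x63*y
    x186 = x111*x185
    x187 = x186*x62
    x188 = x186*x78
    x189 = x*x8
    x190 = x141*x33
    x191 = 16*x180
    x192 = x175*x189 + x178*x22 - x178*x42 - x181*x190 + x181*x191
    x193 = x106*y
    x194 = x23*y
    x195 = x185*x194
    x196 = x1*x109 + x195 - 2*x88
    x197 = 8*vy
    x198 = x0*y
    x199 = x109*x198 - x113*y + x185*x24 + x197*x29 - 2*x89 + 4
    x200 = x196*y + x199
    x201 = x193 + x200
    x202 = x102*x179 + x105*x179 + x121*x201 - x135*x179 + x179*x84 - x179*x95 - x201*x65
    x203 = x122*x123
    x204 = 32*k
    x205 = x36*x91
    x206 = 4*x205
    x207 = c*x206
    x208 = 4*x21
    x209 = x208*x98
    x210 = x181*x31
    x211 = 4*x104
    x212 = x179*x211
    x213 = x101*x31
    x214 = x208*x31
    x215 = x92*x99
    x216 = x101*x215
    x217 = x103*x92
    x218 = x217*x55
    x219 = x179*x23
    x220 = x130*x31
    x221 = x138*x220
    x222 = x140*x220
    x223 = x179*x36
    x224 = x223*x71
    x225 = c*x224
    x226 = x119*x179
    x227 = x46*x96
    x228 = x181*x227
    x229 = x201*x31
    x230 = x149*x23
    x231 = x116*x23
    x232 = 16*x165
    x233 = x*y
    x234 = 6*x108
    x235 = x185*x71
    x236 = x112*x185
    x237 = 6*x162
    x238 = x182*x4
    x239 = x*x23
    x240 = x*x1
    x241 = -vy*x231 - x*x235 + x0*x238 - x111*y + x115*x164*y + x115*x236 + x118*x194 + x155*x198 - x159*x233 + x176*x232 + x177*x232 + x200*x239 - x233*x234 + x233*x237 + y*(x1*x155 - x110 - x111 + x164*x240 + x233*x236 + x238*y)
    x242 = 4*x170
    x243 = x120*x169
    x244 = 32*x20
    x245 = x10*x244
    x246 = 32*x141*x239
    x247 = x10*x41
    x248 = x19*x239
    x249 = x148*x248
    x250 = 16*x249
    x251 = x20*x4
    x252 = 32*x251
    x253 = x4*x40
    x254 = 16*x253
    x255 = -x252 + x254
    x256 = 2*x251
    x257 = -x256
    x258 = 2*x20
    x259 = x10*x258 + x257
    x260 = x130 + 2
    x261 = x260 - x40
    x262 = x*x261
    x263 = x111*x262
    x264 = x263*x62 - x263*x78 + x76*(-x10*x40 - x141*x161 + x249 + x253 + x259)
    x265 = c*x81
    x266 = x252 - x254
    x267 = c*x83
    x268 = c*x
    x269 = x115*x23
    x270 = c*x261
    x271 = x1*x23
    x272 = x*x271
    x273 = x15*x158
    x274 = x*x273 - x116
    x275 = x269*x270 + x270*x272 + x274
    x276 = x275*x65
    x277 = x100*x96
    x278 = x*x105 - x*x135 + x*x84 + x121*x275 + x268*x277 - x268*x94 - x276
    x279 = -x35
    x280 = x17*x279
    x281 = -x280*x4
    x282 = -x31
    x283 = x12*x279
    x284 = x279*x45
    x285 = c*x4
    x286 = x285*(x10*x280 - x161*x282*x283 + x248*x282*x284 + x259 + x281)
    x287 = x260 + x280
    x288 = c*x287
    x289 = x112*x288
    x290 = 2*x288
    x291 = x0*x1*x289 - x273
    x292 = x0*x232 + x0*x286 + x1*x286 - x13*x158 + x163*x289 - x24*x290 + x291
    x293 = x269*x288 + x272*x288 + x274
    x294 = x21*x293
    x295 = x160*x9
    x296 = x1*(x110 + x23*x68) + x107 + x117
    x297 = x161*x37
    x298 = x161*x97
    x299 = x21*x298
    x300 = x145*x31
    x301 = x150*x239
    x302 = x227*x239
    x303 = c*x302
    x304 = x151*x31
    x305 = x104*x214
    x306 = x211*x213
    x307 = c*x31
    x308 = x211*x248
    x309 = x*x9
    x310 = x120*x309
    x311 = x128*x161
    x312 = -x206*x285 + x215*x285*x96 + x218*x4 - x242*x98 + 32*x5
    x313 = x244*x309
    x314 = x309*x41
    x315 = -x142 + x180 + x258*x309 - x309*x40
    x316 = x111*x261
    x317 = x315*x76 + x316*x62 - x316*x78
    x318 = c*y
    x319 = y**3
    x320 = x270*x319
    x321 = x24*y
    x322 = -x197 + x273*y
    x323 = x23*x320 + x270*x321 + x322
    x324 = x323*x65
    x325 = x105*y + x121*x323 - x135*y + x277*x318 - x318*x94 - x324 + x84*y
    x326 = x21*x323
    x327 = x112*x270
    x328 = x285*x315
    x329 = y*(x*x232 + x0*x328 + x1*x328 + x115*x327 - x161*x270 - x231 + x240*x327)
    x330 = x71*y
    x331 = x330*x37
    x332 = x330*x97
    x333 = x21*x332
    x334 = x150*x194
    x335 = x194*x227
    x336 = c*x335
    x337 = x128*x330
    x338 = x19*x194
    x339 = x211*x338
    x340 = x233*x9
    x341 = x160*x205
    x342 = -c*x175*x341 - x160*x175*x21*x98 + x204*x340 + x216*x340 + x218*x340
    x343 = x4*x82
    x344 = x53*x61
    x345 = x344*(x58/(4*x52 + x58) - 1)
    x346 = x345*x68
    x347 = x4*x80
    x348 = 4*x20
    x349 = x239*x348
    x350 = x31*x4
    x351 = x24 + x271 - 2
    x352 = x256*x97
    x353 = x120*x20
    x354 = x161*x353
    x355 = c*x173
    x356 = 2 - x120
    x357 = eps*x170*x356
    x358 = (1/32)*k
    x359 = x31*x93
    x360 = c*q1
    x361 = -x17*x19 + 2
    x362 = x361*x56
    x363 = x360*x362
    x364 = 4*x56
    x365 = x261*x360
    x366 = x62*(-x359*x363 + x364*x68 + x365*x68)
    x367 = x365 + 4*x54 + 2*x55
    x368 = x367*x78
    x369 = x368*x68
    x370 = 16*x361
    x371 = x36*x370
    x372 = x360*x371
    x373 = -x189 - x22*x31 + x31*x372 + x31*x42
    x374 = c**2
    x375 = x261*x374
    x376 = x102 + x105 - x135 - x258*x375 + x353*x375 + x84 - x95
    x377 = eps*x376
    x378 = x377*x4
    x379 = x208*x261
    x380 = x261*x285
    x381 = x261*x4
    x382 = x381*x97
    x383 = x121*x261
    x384 = 2*x4
    x385 = x128*x384
    x386 = x211*x350
    x387 = x251*x31
    x388 = x130*x137
    x389 = x388*x96
    x390 = x261*x9
    x391 = x141*x361
    x392 = -x115*x390 + x24*x391 - x240*x390 + x262*x384 + x271*x391
    x393 = x4*x93
    x394 = x227*x4
    x395 = x251*x46
    x396 = x258*x96
    x397 = x40*x96
    x398 = x20*x40
    x399 = x12*(-2*x34 - x396 + x397 + x398 + 2)
    x400 = x172*x399
    x401 = x20*x356
    x402 = (1/32)*eps
    x403 = x285*x402
    x404 = x1*x9
    x405 = x404*x8
    x406 = x13 + 3*x14 - x25*x271
    x407 = x406*x9
    x408 = x22*x407
    x409 = x179**2
    x410 = x38*x409
    x411 = x407*x42
    x412 = c*x409
    x413 = x412*x48
    x414 = 16*x413
    x415 = x185**2*x23
    x416 = x409*x71
    x417 = -x37*x416 + x404*x63 + x407*x65 - x407*x67 + x413 + x70
    x418 = x415*x62 - x415*x78 + x417*x76
    x419 = x104*x416
    x420 = x409*x47
    x421 = x179*x201
    x422 = x228*x23
    x423 = 2*x236
    x424 = x4*x417
    x425 = -x0*x109 + x0*x424 - 4*x1*x108 + x1*x154 - x1*x159 + x1*x237 + x14*x166 - x158*x86 + x167 + x198*x423 + x200*x330 - x235*y + y*(x1*x423 + x164*x319 - x234*y - x235 + x424*y)
    x426 = x175*x244
    x427 = x223*x33
    x428 = x175*x41
    x429 = x179*x48
    x430 = 16*x429
    x431 = x175*x258 - x175*x40 - x224 + x429
    x432 = x261*x62
    x433 = x185*x23
    x434 = x261*x78
    x435 = x431*x76 + x432*x433 - x433*x434
    x436 = x*x265
    x437 = x*x267
    x438 = x123*x202
    x439 = x285*x431
    x440 = x0*x439 + x1*x439 + x112*x320 - x197*x23 + x198*x327 + x232*y - x270*x330
    x441 = x175*x208
    x442 = x179*x275
    x443 = x120*x175
    x444 = x179*x239
    x445 = x104*x208
    x446 = x101*x212
    x447 = x130*x444
    x448 = x244*x404
    x449 = 32*x194*x223
    x450 = x404*x41
    x451 = x179*x338*x46
    x452 = 16*x451
    x453 = x257 + x258*x404
    x454 = x195*x432 - x195*x434 + x76*(-x223*x330 + x253 - x40*x404 + x451 + x453)
    x455 = -x179
    x456 = x285*(x280*x404 + x281 - x283*x330*x455 + x284*x338*x455 + x453)
    x457 = y**4
    x458 = x0*x456 + x1*x232 + x1*x456 - x14*x158 - x271*x290 + x289*x457 + x291
    x459 = x23*x288*x319 + x288*x321 + x322
    x460 = x193 + x196*y + x199
    x461 = x179*x459
    x462 = x179*x194
    x463 = x130*x462
    x464 = x185*x345
    x465 = x194*x348
    x466 = x330*x353
    x467 = x179*x93
    x468 = x62*(x185*x364 + x185*x365 - x363*x467)
    x469 = x185*x368
    x470 = -x179*x22 + x179*x372 + x179*x42 - x8*y
    x471 = x212*x4
    x472 = x261*y
    x473 = x223*x361
    x474 = -x198*x390 + x24*x473 + x271*x473 - x319*x390 + x384*x472
    x475 = x261**2
    x476 = x360*x475
    x477 = c*x475*x78 + x36*x361*x76 - x476*x61
    x478 = -x371 + x477
    x479 = x267*x478
    x480 = x371 + x477
    x481 = x265*x480
    x482 = x361*x37
    x483 = x482*x9
    x484 = x10*x482
    x485 = x1*x484 - 8
    x486 = x163*x483 + 8*x24 + x485
    x487 = x161*x36
    x488 = x104*x24
    x489 = x24*x96
    x490 = x20*x275
    x491 = x120*x251
    x492 = x239*x46
    x493 = x137*x19
    x494 = x20*x493
    x495 = c*x174
    x496 = x158 + x404*x482 + x484
    x497 = x330*x36
    x498 = x104*x160
    x499 = x194*x96
    x500 = x194*x20
    x501 = x20*x323
    x502 = x194*x46
    x503 = x*x130
    x504 = x137*x503
    x505 = x345*x82
    x506 = x345*x80
    x507 = x173*x399
    x508 = x278*x401
    x509 = (1/32)*c*x5
    x510 = x361*x74
    x511 = 32*x19 - x41 + 32
    x512 = x82*(-q1*x371 + x261*x368 + x511 - x62*(x261*x364 + x476 - x510*x93))
    x513 = x80*(q1*x283*x370 - x287*x368 + x511 + x62*(2*x283*x510 + x287*x364 + x287*x365))
    x514 = x21*x361
    x515 = x279*x514
    x516 = x270*x92
    x517 = x65*x96
    x518 = x280*x361*x517
    x519 = x270*x397
    x520 = x21*x40
    x521 = x125*x99
    x522 = 2*x521
    x523 = x100*x20
    x524 = x12*x355
    x525 = (1/128)*x4
    x526 = 8*x271 + x457*x483 + x485
    x527 = x104*x271
    x528 = x271*x96
    x529 = x325*x401
    x530 = x206*y
    x531 = x130*y
    x532 = eps*x20**2*x374
    x533 = x270*x344 - x368 + 16*x75
    x534 = (1/4)*x356*x532*(-x18*x96 + 1)
    x535 = x61*(-c*x362*x53*x93 + 8*x365*x56 + x374*x475*x53 + 4*x57)
    x536 = x367**2*x58*x77
    x537 = -64*x21 + x372 + 32*x67
    x538 = x100*x19
    return [(1/128)*x122**2*x123 + (1/128)*x174*(x101*x133 + x102*x27 + x105*x27 + x119*x143 + x124*x26 - x129*x49 + x132*x49 + x133*x21 - x135*x27 - x136*x138 - x136*x140 + x144*x146 - x144*x151 - x147*x149 - x168*x169 + x168*x171 - x27*x95) + (1/128)*x81*(x11 + x28 - x39 - x43 + x51 + x7 + x79) - 1/128*x83*(-x11 - x28 + x39 + x43 - x51 + x6 + x79),
            (1/128)*x173*(x119*x225 - x128*x210*x71 + x131*x179*x214 + x143*x201 + x146*x226 + x146*x229 - x147*x228 - x151*x226 - x151*x229 + x178*x204 - x178*x207 - x178*x209 + x178*x216 + x178*x218 - x201*x230 + x210*x211*x47 + x212*x213*x23 - x219*x221 - x219*x222 - x241*x242 + x241*x243) + (1/128)*x202*x203 + (1/128)*x81*(x183 + x187 - x188 + x192) + (1/128)*x83*(-x183 - x187 + x188 + x192),
            -1/128*x173*(-x10*x204 + x10*x207 + x10*x209 - x10*x216 - x10*x218 - x143*x293 + x221*x239 + x222*x239 + x230*x293 - x239*x305 - x239*x306 + x242*x292 - x243*x292 + x293*x304 - x293*x310*x65 + x294*x295 - x294*x300 - x296*x297 - x296*x299 + x296*x301 + x296*x303 - x307*x308 + x307*x311 + x312) + (1/128)*x203*x278 + (1/128)*x265*(x245 - x246 - x247 + x250 + x255 + x264) - 1/128*x267*(-x245 + x246 + x247 - x250 + x264 + x266),
            (1/128)*x173*(x119*x331 + x119*x333 - x119*x334 - x119*x336 + x143*x323 - x194*x221 - x194*x222 + x194*x305 + x194*x306 - x230*x323 - x242*x329 + x243*x329 - x295*x326 + x300*x326 - x304*x323 - x307*x337 + x307*x339 + x310*x324 + x342) + (1/128)*x203*x325 + (1/128)*x265*y*(-x190 + x191 + x313 - x314 + x317) - 1/128*x267*y*(x190 - x191 - x313 + x314 + x317),
            x358*(x122*x357 - x343*x346 + x346*x347 + x355*(x148*x251 + x227*x350 - x31*x352 + x349*x351 + x349 - x350*x93 - x351*x354 - x354)),
            -1/128*x122*x378 + (1/128)*x343*(x366 - x369 + x373) + (1/128)*x347*(-x366 + x369 + x373) + (1/128)*x355*(-x119*x352 - x119*x393 + x119*x394 + x119*x395 + x148*x380*x96 + x150*x261*x350 - x161*x383 - x19*x386 - x211*x387 + x239*x379 - x242*x392 + x243*x392 + x31*x385 + x350*x389 - x359*x380 - x382*x66 - x386*x96 + x387*x388),
            -x403*(x122*x401 + x31*x400),
            0,
            (1/128)*x123*x202**2 + (1/128)*x174*(x101*x419 + x102*x407 + x105*x407 + x124*x406 - x129*x412 + x132*x412 - x135*x407 - x138*x420 - x140*x420 + x146*x421 - x151*x421 - x169*x425 + x171*x425 + x201*x225 - x201*x422 + x21*x419 - x407*x95) + (1/128)*x81*(x405 + x408 - x410 - x411 + x414 + x418 + x7) - 1/128*x83*(-x405 - x408 + x410 + x411 - x414 + x418 + x6),
            (1/128)*x173*(x*x243*x440 - x138*x447 - x140*x447 + x146*x442 - x151*x442 - x160*x170*x440 + x181*x308 - x181*x311 + x201*x297 + x201*x299 - x201*x301 - x201*x303 + x225*x275 + x239*x446 - x275*x422 - x275*x441 + x276*x443 + x342 + x444*x445) + (1/128)*x278*x438 + (1/128)*x436*(x426 - x427 - x428 + x430 + x435) - 1/128*x437*(-x426 + x427 + x428 - x430 + x435),
            -1/128*x173*(x138*x463 + x140*x463 - x146*x461 + x151*x461 + x181*x337 - x181*x339 - x194*x446 - x204*x404 + x207*x404 + x209*x404 - x216*x404 - x218*x404 - x225*x459 + x242*x458 - x243*x458 + x312 - x331*x460 - x333*x460 + x334*x460 + x336*x460 + x422*x459 + x441*x459 - x443*x459*x65 - x445*x462) + (1/128)*x265*(x255 + x448 - x449 - x450 + x452 + x454) - 1/128*x267*(x266 - x448 + x449 + x450 - x452 + x454) + (1/128)*x325*x438,
            x358*(x202*x357 - x343*x464 + x347*x464 + x355*(-x179*x352 - x179*x393 + x179*x394 + x179*x395 + x351*x465 - x351*x466 + x465 - x466)),
            -1/128*x202*x378 + (1/128)*x343*(x468 - x469 + x470) + (1/128)*x347*(-x468 + x469 + x470) + (1/128)*x355*(x150*x179*x381 + x179*x227*x380 + x179*x251*x388 + x179*x385 + x179*x389*x4 - x184*x382 - x19*x471 + x194*x379 - x201*x352 - x201*x393 + x201*x394 + x201*x395 - x212*x251 - x242*x474 + x243*x474 - x330*x383 - x380*x467 - x471*x96),
            -x403*(x179*x400 + x202*x401),
            0,
            (1/128)*x123*x278**2 + (1/128)*x24*x479 - 1/128*x24*x481 + (1/128)*x495*(-x128*x24 + x130*x488 + x217*x489 - x24*x494 + x256*x486 + x258*x488 - x275*x302 + x275*x487 + x298*x490 - x486*x491 - x489*x493 - x490*x492),
            (1/128)*x123*x278*x325 - 1/128*x194*x436*x480 + (1/128)*x194*x437*x478 + (1/128)*x355*(-x120*x233*x256*x496 + x160*x251*x496*y - x275*x335 + x275*x497 + x298*x501 - x302*x323 - x311*y + x323*x487 + x332*x490 + x338*x498 - x490*x502 - x492*x501 + x498*x499 + x498*x500 - x499*x504 - x500*x504),
            x509*(eps*x508 + x*x507 - x262*x505 + x262*x506),
            -x525*(x268*x512 + x268*x513 + x278*x377 - x524*(-x*x516 - x*x518 + x*x519 + x*x522 + x160*x515 - x19*x341 - x20*x341 - x262*x517 + x262*x520 + x277*x503 - x293*x396 + x293*x397 + x293*x398 - x293*x92 - x341*x96 + x503*x523)),
            -x403*(x*x400 + x508),
            0,
            (1/128)*x123*x325**2 + (1/128)*x271*x479 - 1/128*x271*x481 + (1/128)*x495*(-x128*x271 + x130*x527 + x217*x528 + x256*x526 + x258*x527 - x271*x494 - x323*x335 + x323*x497 + x332*x501 - x491*x526 - x493*x528 - x501*x502),
            x509*(eps*x529 - x472*x505 + x472*x506 + x507*y),
            -x525*(x318*x512 + x318*x513 + x325*x377 - x524*(-x19*x530 - x205*x348*y + x277*x531 - x396*x459 + x397*x459 + x398*x459 - x459*x92 - x472*x517 + x472*x520 + 4*x515*y - x516*y - x518*y + x519*y + x522*y + x523*x531 - x530*x96)),
            -x403*(x400*y + x529),
            0,
            (1/8)*k**2*(x356**2*x532 + x505 - x506),
            -x358*(x21*x356*x377 + x355*x399 - x80*(x533 + 16) + x82*(x533 - 16)),
            -k*x534,
            0,
            (1/128)*eps*x376**2 + (1/128)*x12*x495*(x130*x205 - x20*x538 + x205*x258 + x261*x517 - x261*x520 - x397*x514 + x514*x92 + x516 - x519 - x521 - x538*x96 + x94*x96) - 1/128*x80*(-x535 + x536 + x537) - 1/128*x82*(x535 - x536 + x537),
            c*x402*(x376*x401 + x400),
            0,
            x534,
            0,
            0]


def grad_phi(x, y, vx, vy, q, q1, q2, u, k, c, eps, etp, etn, wd, wr, w0, w1, w2, w3, w4, w5, w6):
    x0 = x**2
    x1 = y**2
    x2 = x0 + x1
    x3 = np.sqrt(x2)
    x4 = 1/x3
    x5 = vx*x + vy*y
    x6 = q1 - x4*x5
    x7 = 1/wd
    x8 = x6*x7
    x9 = np.tanh((1/2)*x8)
    x10 = c*(x9 + 1)
    x11 = 2*k*(q - x3 + 1) + x10*x6
    x12 = 2*x11/x2**(3/2)
    x13 = w2*x0
    x14 = 1/x2
    x15 = 4*k
    x16 = x*x15
    x17 = vx - x*x14*x5
    x18 = 2*x10
    x19 = x9**2 - 1
    x20 = -x17
    x21 = -x19*x8
    x22 = w3*y
    x23 = w2*x
    x24 = vy - x14*x5*y
    x25 = x19*x8
    x26 = x14*(-c*x24*x25 + x15*y + x18*x24)
    x27 = 2*x9 + 2
    x28 = (1/4)*c
    x29 = x28*(x21 + x27)
    x30 = x14*x29
    x31 = x28*x4*(-x25 + x27)
    return [(1/4)*w2*x*x14*(c*x17*x19*x6*x7 - x16 - x17*x18) + (1/2)*w2*x11*x4 - 1/4*x12*x13 - 1/4*x22*(x*x12 - x14*(c*x20*x21 - x16 + x18*x20)),
            (1/4)*w3*(-x1*x12 + 2*x11*x4 - x26*y) - 1/4*x12*x23*y - 1/4*x23*x26,
            w0 - x*x22*x30 - x13*x30,
            w1 - w3*x1*x30 - x14*x23*x29*y,
            k*x4*(x22 + x23),
            w4 + x22*x31 + x23*x31,
            w5,
            w6]


def hess_phi(x, y, vx, vy, q, q1, q2, u, k, c, eps, etp, etn, wd, wr, w0, w1, w2, w3, w4, w5, w6):
    x0 = w2*x
    x1 = x**2
    x2 = y**2
    x3 = x1 + x2
    x4 = x3**(-3/2)
    x5 = np.sqrt(x3)
    x6 = vx*x
    x7 = vy*y
    x8 = x6 + x7
    x9 = 1/x5
    x10 = q1 - x8*x9
    x11 = 1/wd
    x12 = x10*x11
    x13 = np.tanh((1/2)*x12)
    x14 = x13 + 1
    x15 = c*x14
    x16 = 2*k*(q - x5 + 1) + x10*x15
    x17 = 6*x16
    x18 = x17*x4
    x19 = x17/x3**(5/2)
    x20 = w2*x**3
    x21 = 1/x3
    x22 = 4*k
    x23 = x*x22
    x24 = x21*x8
    x25 = x*x24
    x26 = vx - x25
    x27 = 2*x15
    x28 = x13**2 - 1
    x29 = x12*x28
    x30 = c*x29
    x31 = x23 + x26*x27 - x26*x30
    x32 = x21*x31
    x33 = x3**(-2)
    x34 = x31*x33
    x35 = 2*x34
    x36 = w2*x1
    x37 = -x22*x9
    x38 = x1*x4
    x39 = x26**2
    x40 = x21*x28
    x41 = 2*x11
    x42 = x40*x41
    x43 = c*x42
    x44 = 3*x24
    x45 = -x1*x44 + 3*x6 + x7
    x46 = 2*x4
    x47 = x15*x46
    x48 = x30*x4
    x49 = x10*x13/wd**2
    x50 = x40*x49
    x51 = c*x50
    x52 = x9*(x22*x38 + x37 - x39*x43 + x39*x51 + x45*x47 - x45*x48)
    x53 = x16*x46
    x54 = x1*x19
    x55 = w3*y
    x56 = w2*y
    x57 = vy - x24*y
    x58 = x22*y + x27*x57 - x30*x57
    x59 = w2*x21
    x60 = x0*y
    x61 = x33*x58
    x62 = x4*y
    x63 = vx*y + vy*x - 3*x25*y
    x64 = x26*x40
    x65 = x41*x64
    x66 = c*x57
    x67 = x49*x64
    x68 = x23*x62 + x47*x63 - x48*x63 - x65*x66 + x66*x67
    x69 = x0*x9
    x70 = x19*x2
    x71 = x*y
    x72 = x9*y
    x73 = 2*x13 - x29 + 2
    x74 = x21*x73
    x75 = x33*x73
    x76 = x14*x46
    x77 = -2*x14*x9 + x29*x9
    x78 = -x*x65 + x*x67 + x1*x76 - x29*x38 + x77
    x79 = x55*x9
    x80 = (1/4)*c
    x81 = x*x55
    x82 = -x*x29*x4 + x*x76 - x65 + x67
    x83 = x80*y
    x84 = k*x9
    x85 = x73*x9
    x86 = x4*x73
    x87 = x11*(-x12*x13 + 2)
    x88 = x64*x87
    x89 = 2*x58
    x90 = x33*x89
    x91 = x2*x4
    x92 = x57**2
    x93 = -x2*x44 + x6 + 3*x7
    x94 = x22*x91 + x37 - x43*x92 + x47*x93 - x48*x93 + x51*x92
    x95 = y**3
    x96 = w3*x21
    x97 = w3*x75
    x98 = x42*x57
    x99 = x50*x57
    x100 = -x29*x62 + x76*y - x98 + x99
    x101 = x*x80
    x102 = x2*x76 - x29*x91 + x77 - x98*y + x99*y
    x103 = x40*x87
    x104 = x103*x57
    x105 = x0 + x55
    x106 = x105*x28*x80*x87
    x107 = x103*x105
    return [-1/2*w2*x32 - 1/4*x0*x18 + (1/4)*x0*x52 + (1/4)*x19*x20 + (1/4)*x35*x36 + (1/4)*x55*(x*x35 + x52 - x53 + x54),
            (1/4)*w3*(-x*x53 + x*x70 + x2*x34 - x32 + x61*x71 + x68*x72) + (1/4)*x34*x60 + (1/4)*x36*x61 - 1/4*x53*x56 + (1/4)*x54*x56 - 1/4*x58*x59 + (1/4)*x68*x69,
            x80*(-x0*x74 + x1*x55*x75 + x20*x75 + x69*x78 + x78*x79),
            x83*(x36*x75 - x59*x73 + x69*x82 + x75*x81 + x79*x82),
            -x84*(-w2 + x1*x59 + x21*x81),
            x80*(-w2*x38*x73 + w2*x85 + x0*x88 + x55*x88 - x81*x86),
            0,
            0,
            (1/4)*w3*(-x18*y + x19*x95 + x2*x90 - x21*x89 + x72*x94) - 1/4*x0*x53 + (1/4)*x0*x70 + (1/4)*x60*x90 + (1/4)*x69*x94,
            x101*(x100*x69 + x100*x79 + x2*x97 + x60*x75 - x73*x96),
            x80*(x0*x2*x75 + x102*x69 + x102*x79 - x55*x74 + x95*x97),
            -x84*(-w3 + x2*x96 + x21*x60),
            x80*(-w3*x73*x91 + w3*x85 + x0*x104 + x104*x55 - x60*x86),
            0,
            0,
            -x106*x38,
            -x106*x4*x71,
            0,
            x101*x107,
            0,
            0,
            -x106*x91,
            0,
            x107*x83,
            0,
            0,
            0,
            0,
            0,
            0,
            -x106*x9,
            0,
            0,
            0,
            0,
            0]


def grad_F(x, y, vx, vy, q, q1, q2, u, k, c, eps, etp, etn, wd, wr):
    x0 = x**2 + y**2
    x1 = 1/np.sqrt(x0)
    x2 = vx*x + vy*y
    x3 = x2/x0
    x4 = vx - x*x3
    x5 = 1/wd
    x6 = q1 - x1*x2
    x7 = np.tanh((1/2)*x5*x6)
    x8 = (1/2)*c*(x7 + 1)
    x9 = x7**2 - 1
    x10 = vy - x3*y
    x11 = -x5*x6*x9 + 2*x7 + 2
    x12 = (1/4)*c
    x13 = -x1*x11*x12
    return [x1*((1/4)*c*x4*x5*x6*x9 - k*x - x4*x8),
            x1*((1/4)*c*x10*x5*x6*x9 - k*y - x10*x8),
            x*x13,
            x13*y,
            k,
            x11*x12,
            0,
            0]


def hess_F(x, y, vx, vy, q, q1, q2, u, k, c, eps, etp, etn, wd, wr):
    x0 = x**2
    x1 = y**2
    x2 = x0 + x1
    x3 = 1/np.sqrt(x2)
    x4 = -k*x3
    x5 = x2**(-3/2)
    x6 = k*x5
    x7 = vx*x
    x8 = vy*y
    x9 = x7 + x8
    x10 = 1/x2
    x11 = x10*x9
    x12 = x*x11
    x13 = vx - x12
    x14 = x13**2
    x15 = (1/2)*c
    x16 = 1/wd
    x17 = q1 - x3*x9
    x18 = x16*x17
    x19 = np.tanh((1/2)*x18)
    x20 = x19**2 - 1
    x21 = x16*x20
    x22 = x10*x21
    x23 = x15*x22
    x24 = 3*x11
    x25 = x5*(-x0*x24 + 3*x7 + x8)
    x26 = x19 + 1
    x27 = x15*x26
    x28 = (1/4)*c
    x29 = x18*x20
    x30 = x10*x17*x19*x20/wd**2
    x31 = x28*x30
    x32 = x*y
    x33 = vx*y + vy*x - 3*x12*y
    x34 = x27*x5
    x35 = vy - x11*y
    x36 = x29*x5
    x37 = x28*x36
    x38 = x13*x30
    x39 = 2*x26
    x40 = x39*x5
    x41 = 2*x22
    x42 = x13*x41
    x43 = x29*x3 - x3*x39
    x44 = x28*y
    x45 = -x18*x19 + 2
    x46 = x28*x45
    x47 = x21*x46
    x48 = x3*x47
    x49 = x35**2
    x50 = -x1*x24 + x7 + 3*x8
    x51 = x35*x41
    x52 = x30*x35
    x53 = x*x28
    x54 = x22*x46
    x55 = x21*x3*x45
    return [x0*x6 - x14*x23 + x14*x31 + x25*x27 - x25*x28*x29 + x4,
            -x13*x23*x35 + x28*x35*x38 + x32*x6 + x33*x34 - x33*x37,
            x28*(x*x38 - x*x42 - x0*x36 + x0*x40 + x43),
            x44*(-x*x36 + x*x40 + x38 - x42),
            0,
            x13*x48,
            0,
            0,
            x1*x6 - x23*x49 + x31*x49 + x34*x50 - x37*x50 + x4,
            x53*(-x36*y + x40*y - x51 + x52),
            x28*(-x1*x36 + x1*x40 + x43 - x51*y + x52*y),
            0,
            x35*x48,
            0,
            0,
            -x0*x54,
            -x32*x54,
            0,
            x53*x55,
            0,
            0,
            -x1*x54,
            0,
            x44*x55,
            0,
            0,
            0,
            0,
            0,
            0,
            -x47,
            0,
            0,
            0,
            0,
            0]


def grad_Ll(x, y, vx, vy, q, q1, q2, u, k, c, eps, etp, etn, wd, wr):
    x0 = 1/np.sqrt(x**2 + y**2)
    return [x*x0,
            x0*y,
            0,
            0,
            0,
            0,
            0,
            0]


def hess_Ll(x, y, vx, vy, q, q1, q2, u, k, c, eps, etp, etn, wd, wr):
    x0 = x**2
    x1 = y**2
    x2 = x0 + x1
    x3 = 1/np.sqrt(x2)
    x4 = 1/x2
    return [-x3*(x0*x4 - 1),
            -x*y/x2**(3/2),
            0,
            0,
            0,
            0,
            0,
            0,
            -x3*(x1*x4 - 1),
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0,
            0]

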