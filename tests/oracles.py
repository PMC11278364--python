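"""Brute-force oracles shared by the compositing tests.

These recompute, per pixel and per instance, what the renderer computes in
vectorized form: inverse-map each output pixel into the cutout's frame,
bilinearly sample the binary alpha, and threshold at 0.5.
"""

import math

import numpy as np

from maskcycle.cutpaste import bilinear_sample


def coverage_oracle(background_shape, cutouts, instances):
    H, W = background_shape
    covered = np.zeros((H, W), dtype=np.uint8)
    for inst in instances:
        alpha = cutouts[inst.cutout_index].alpha.astype(np.float64)
        if inst.hflip:
            alpha = alpha[:, ::-1]
        if inst.vflip:
            alpha = alpha[::-1, :]
        h, w = alpha.shape
        if inst.scale == 1.0 and inst.rotation == 0.0:
            out_h, out_w = h, w
            inv = np.eye(2)
            c_src = ((h - 1) / 2.0, (w - 1) / 2.0)
            c_out = c_src
        else:
            theta = math.radians(inst.rotation)
            cos_t, sin_t = math.cos(theta), math.sin(theta)
            out_h = int(math.ceil((h * abs(cos_t) + w * abs(sin_t)) * inst.scale)) + 1
            out_w = int(math.ceil((w * abs(cos_t) + h * abs(sin_t)) * inst.scale)) + 1
            inv = np.array([[cos_t, sin_t], [-sin_t, cos_t]]) / inst.scale
            c_src = ((h - 1) / 2.0, (w - 1) / 2.0)
            c_out = ((out_h - 1) / 2.0, (out_w - 1) / 2.0)
        top = int(round(inst.center[0] - (out_h - 1) / 2.0))
        left = int(round(inst.center[1] - (out_w - 1) / 2.0))
        for oy in range(out_h):
            ry = top + oy
            if not (0 <= ry < H):
                continue
            for ox in range(out_w):
                rx = left + ox
                if not (0 <= rx < W):
                    continue
                dy, dx = oy - c_out[0], ox - c_out[1]
                sr = inv[0, 0] * dy + inv[0, 1] * dx + c_src[0]
                sc = inv[1, 0] * dy + inv[1, 1] * dx + c_src[1]
                if bilinear_sample(alpha, np.float64(sr), np.float64(sc)) >= 0.5:
                    covered[ry, rx] = 1
    return covered
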