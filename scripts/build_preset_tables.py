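#!/usr/bin/env python
"""Reconstruct the frozen reference FAM/DDW intensity tables.

The reference device publishes only nine summary statistics of its 25-tube
measurement (mean/min/max of FAM brightness, DDW brightness, and their
per-tube ratio), not the per-tube values.  This script constructs one joint
5x5 FAM/DDW table pair satisfying all nine simultaneously and prints it;
the result is frozen in ``quadfluor.synth`` as the ``table3`` preset and
verified there by direct recomputation.

Construction: four extreme tubes are pinned first — the FAM minimum
carries the ratio minimum, the FAM maximum carries the ratio maximum, and
the DDW minimum/maximum tubes get hand-chosen ratios (the DDW maximum is
paired with a high ratio because DDW's tight range leaves almost no spread
to generate the required FAM-sum covariance elsewhere).  The remaining 21
tubes use a skewed DDW pattern hugging the 12.00 floor and a ratio pattern
spread over the gain range, sort-matched and finished with a rank-1
correction so the FAM sum lands exactly.
"""

import numpy as np

F_MEAN, F_MIN, F_MAX = 55.23, 34.48, 85.11
D_MEAN, D_MIN, D_MAX = 12.27, 12.00, 14.03
R_MEAN, R_MIN, R_MAX = 4.48, 2.84, 6.37


def build() -> tuple[np.ndarray, np.ndarray]:
    r3, r4 = 3.0, 5.9
    fixed = np.array([
        (F_MIN, F_MIN / R_MIN),
        (F_MAX, F_MAX / R_MAX),
        (D_MIN * r3, D_MIN),
        (D_MAX * r4, D_MAX),
    ])
    n = 21
    sf = 25 * F_MEAN - fixed[:, 0].sum()
    sd = 25 * D_MEAN - fixed[:, 1].sum()
    sr = 25 * R_MEAN - (R_MIN + R_MAX + r3 + r4)

    rng = np.random.default_rng(20211022)
    p = np.array([0.02, 0.025, 0.03, 0.035, 0.04, 0.05, 0.06, 0.07, 0.08,
                  0.09, 0.10, 0.11, 0.12, 0.13, 0.16, 0.20, 0.26, 0.33,
                  0.42, 0.52, 0.62])
    d = 12.0 + p * (sd - 12.0 * n) / p.sum()
    r = np.linspace(3.05, 6.20, n)
    lo = r[:14].copy()
    rng.shuffle(lo)
    r[:14] = lo
    r = r - r.mean() + sr / n
    dd = d - d.mean()
    r = r + (sf - (d * r).sum()) / (dd * dd).sum() * dd
    f = d * r
    assert d.min() > 12.005 and d.max() < 13.9
    assert r.min() > 2.90 and r.max() < 6.30
    assert f.min() > 35.0 and f.max() < 84.5

    order = rng.permutation(25)
    fam = np.round(np.concatenate([fixed[:, 0], f])[order].reshape(5, 5), 6)
    ddw = np.round(np.concatenate([fixed[:, 1], d])[order].reshape(5, 5), 6)
    return fam, ddw


def main() -> None:
    fam, ddw = build()
    gains = fam / ddw
    for name, arr, tgt in [("FAM", fam, (F_MEAN, F_MIN, F_MAX)),
                           ("DDW", ddw, (D_MEAN, D_MIN, D_MAX)),
                           ("gain", gains, (R_MEAN, R_MIN, R_MAX))]:
        stats = np.array([arr.mean(), arr.min(), arr.max()])
        assert np.all(np.abs(stats - np.array(tgt)) < 0.005), (name, stats)
        print(f"{name:>5}: mean {stats[0]:.4f}  min {stats[1]:.4f}  "
              f"max {stats[2]:.4f}  (targets {tgt})")
    np.set_printoptions(precision=6, suppress=True, floatmode="fixed")
    print("FAM =\n", fam)
    print("DDW =\n", ddw)

    from quadfluor.synth import table3_preset
    pf, pd_ = table3_preset()
    assert np.array_equal(pf.values, fam) and np.array_equal(pd_.values, ddw)
    print("matches the frozen quadfluor.synth tables")


if __name__ == "__main__":
    main()
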