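"""Independent brute-force oracle for the iTRAQ quantitation path.

Recomputes every ratio, population moment, Z-score, protein mean and
vector norm from raw reporter intensities in one unoptimized pure-Python
pass (math module only, no numpy/pandas), deliberately sharing no code
with the package implementation.
"""

import math

RATIOS = {"r0": ("116", "114"), "r1": ("117", "115"), "r2": ("115", "114"), "r3": ("117", "116")}


def bruteforce_protein_stats(psms, scale):
    """Map protein_id -> (Z0..Z3, m_diff, m_rep, d_scaled, direction, v_diff,
    fold_change) computed from scratch from PSM reporter intensities.

    PSMs with any non-positive channel are skipped; population mean/SD
    (denominator n) are fit on the quantifiable PSMs; shared PSMs count
    toward every mapped protein.
    """
    quantifiable = []
    for psm in psms:
        inten = psm.reporter_intensities
        if inten is None or any(inten[c] <= 0 for c in ("114", "115", "116", "117")):
            continue
        ratios = {
            name: math.log2(inten[num] / inten[den]) for name, (num, den) in RATIOS.items()
        }
        quantifiable.append((psm, ratios))

    moments = {}
    for name in RATIOS:
        values = [r[name] for _, r in quantifiable]
        n = len(values)
        mean = sum(values) / n
        var = sum((v - mean) ** 2 for v in values) / n
        moments[name] = (mean, math.sqrt(var))

    by_protein = {}
    for psm, ratios in quantifiable:
        z = {
            name: (ratios[name] - moments[name][0]) / moments[name][1] for name in RATIOS
        }
        for pid in psm.protein_ids:
            by_protein.setdefault(pid, []).append(z)

    out = {}
    for pid, zs in by_protein.items():
        Z = [sum(z[name] for z in zs) / len(zs) for name in ("r0", "r1", "r2", "r3")]
        m_diff = math.sqrt(Z[0] ** 2 + Z[1] ** 2)
        m_rep = math.sqrt(Z[2] ** 2 + Z[3] ** 2)
        d_scaled = (m_diff - m_rep) / scale
        direction = 1 if Z[0] + Z[1] >= 0 else -1
        out[pid] = {
            "Z": Z,
            "m_diff": m_diff,
            "m_rep": m_rep,
            "d_scaled": d_scaled,
            "direction": direction,
            "v_diff": direction * d_scaled,
            "fold_change": 2.0 ** ((Z[0] + Z[1]) / 2.0),
        }
    return out
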