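"""Independent brute-force transcriptions of the defining formulas.

These are deliberately literal, slow, dictionary-based implementations
used only as cross-checks; they share no code with the package internals.
"""

import math

from scipy.stats import f as f_dist

from cubkit.genetic_code import (
    CODON_TO_AA,
    FAMILIES,
    FAMILY_SIZE,
    SENSE_CODONS,
)


def rscu_oracle(counts: dict[str, int]) -> dict[str, float]:
    """RSCU_ij = k_i * x_ij / sum_j x_ij, literally."""
    out = {}
    for aa, fam in FAMILIES.items():
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            continue
        for c in fam:
            out[c] = FAMILY_SIZE[aa] * counts.get(c, 0) / total
    return out


def _family_f(counts: dict[str, int], aa: str, mode: str) -> float | None:
    fam = FAMILIES[aa]
    n = sum(counts.get(c, 0) for c in fam)
    if n == 0:
        return None
    sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in fam)
    if mode == "frequencies":
        return sum_p2
    if n < 2:
        return None
    f_hat = (n * sum_p2 - 1) / (n - 1)
    return f_hat if f_hat > 0 else None


def enc_oracle(counts: dict[str, int], mode: str = "counts") -> float:
    """ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with class-average homozygosities.

    Assumes every degeneracy class has usable data (callers generate such
    tables); caps at 61.
    """
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, k in FAMILY_SIZE.items():
        if k < 2:
            continue
        f = _family_f(counts, aa, mode)
        if f is not None:
            class_f[k].append(f)
    value = 2.0
    for k, n_aa in ((2, 9), (3, 1), (4, 5), (6, 3)):
        fbar = sum(class_f[k]) / len(class_f[k])
        value += n_aa / fbar
    return min(max(value, 1.0), 61.0)


def cai_oracle(counts: dict[str, int], w: dict[str, float]) -> float:
    """Geometric mean of weights over codons, excluding ATG, TGG and stops."""
    log_sum = 0.0
    n = 0
    for codon in SENSE_CODONS:
        aa = CODON_TO_AA[codon]
        if FAMILY_SIZE[aa] < 2:
            continue
        x = counts.get(codon, 0)
        log_sum += x * math.log(w[codon])
        n += x
    return math.exp(log_sum / n)


def ols_oracle(x, y):
    """Closed-form simple OLS and Pearson r from the sum formulas, with the
    F-test p-value of the regression."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    r2 = r * r
    f_stat = r2 * (n - 2) / (1 - r2)
    p = float(f_dist.sf(f_stat, 1, n - 2))
    return {"slope": slope, "intercept": intercept, "r": r, "r2": r2, "p": p}
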