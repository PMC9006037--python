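"""Independent brute-force oracles used to check the implementation.

Deliberately written without numpy and without any of the package's
closed forms: covariances are centred sums in exact rational arithmetic
(fractions.Fraction), so the oracle cannot share a bug with the
production path (which goes through np.cov on floats).
"""

from fractions import Fraction


def cov_oracle(x, y):
    """Population covariance (divide by n) as an exact Fraction."""
    n = len(x)
    assert n == len(y) and n > 0
    xs = [Fraction(int(v)) if float(v).is_integer() else Fraction(str(v)) for v in x]
    ys = [Fraction(int(v)) if float(v).is_integer() else Fraction(str(v)) for v in y]
    mx = sum(xs, Fraction(0)) / n
    my = sum(ys, Fraction(0)) / n
    return sum((a - mx) * (b - my) for a, b in zip(xs, ys)) / n


def selection_differential_oracle(trait, raw_fitness):
    """cov(trait, fitness / mean fitness), exact rational arithmetic."""
    n = len(raw_fitness)
    total = sum(int(f) for f in raw_fitness)
    assert total > 0, "mean fitness must be positive"
    mean = Fraction(total, n)
    rel = [Fraction(int(f)) / mean for f in raw_fitness]
    return cov_oracle_fractions([Fraction(int(t)) for t in trait], rel)


def cov_oracle_fractions(xs, ys):
    """cov for sequences already held as Fractions."""
    n = len(xs)
    mx = sum(xs, Fraction(0)) / n
    my = sum(ys, Fraction(0)) / n
    return sum((a - mx) * (b - my) for a, b in zip(xs, ys)) / n
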