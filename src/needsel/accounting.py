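"""Sample-accounting arithmetic for panel extracts.

Small, exact helpers for the bookkeeping every panel analysis reports:
how many observations survive the exclusions, what share of the raw pool
that is, the average number of observations contributed per individual,
and how much of the first wave is still present in the last one.
"""

from __future__ import annotations

__all__ = ["final_sample", "retained_share", "obs_per_person", "wave_retention"]


def final_sample(total_obs: int, *exclusions: int) -> int:
    """Observations remaining after subtracting each exclusion count."""
    n = total_obs - sum(exclusions)
    if n < 0:
        raise ValueError("exclusions exceed the total")
    return n


def retained_share(retained: int, total: int, ndigits: int = 1) -> float:
    """Percentage of the raw pool retained, rounded for reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * retained / total, ndigits)


def obs_per_person(n_obs: int, n_individuals: int, ndigits: int = 1) -> float:
    """Average observations contributed per individual."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    return round(n_obs / n_individuals, ndigits)


def wave_retention(final_wave_n: int, first_wave_n: int, ndigits: int = 1) -> float:
    """Share (percent) of first-wave respondents still present at the end."""
    return retained_share(final_wave_n, first_wave_n, ndigits)
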