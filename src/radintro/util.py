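"""Small shared utilities."""

from __future__ import annotations


def fisher_association(table_2x2) -> dict:
    """Fisher's exact test on a 2x2 contingency table.

    Generic helper for small-count association questions, e.g. whether
    hybrid individuals are found at mixed-species rather than
    single-species sites.  Returns the odds ratio and two-sided p-value.
    """
    from scipy.stats import fisher_exact

    odds, p = fisher_exact(table_2x2, alternative="two-sided")
    return {"odds_ratio": float(odds), "p_value": float(p)}


def mismatch_percent(n_mismatches: int, read_length: int) -> float:
    """Per-read divergence implied by an alignment mismatch allowance.

    Mapping reads of one species against the other's draft genome requires
    choosing how many mismatches to tolerate; expressing the allowance as a
    percentage of the read length makes thresholds comparable across read
    lengths (e.g. 10 mismatches over a 117-bp read is a divergence
    threshold of 8.55%).
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if n_mismatches < 0:
        raise ValueError("n_mismatches must be non-negative")
    return round(100.0 * n_mismatches / read_length, 2)
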