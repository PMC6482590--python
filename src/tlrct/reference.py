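"""Reported headline counts of the reference trial.

These raw counts anchor the simulator's default composition (catalog size,
own-brand fractions, completion and missingness rates) and let the derived
shares be recomputed from numerators/denominators rather than restated.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceCounts", "REFERENCE", "share_pct"]


def share_pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage share of a count, rounded as printed in trial reports."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


@dataclass(frozen=True)
class ReferenceCounts:
    """Raw counts from the reference trial report."""

    n_recruited: int = 496
    n_complete_data: int = 208
    n_withdrawn: int = 3
    products_total: int = 438
    products_own_brand: int = 317
    purchases_total: int = 10416
    purchases_own_brand: int = 8263
    calibration_sample_products: int = 406
    missing_by_period: tuple[int, int, int] = (111, 258, 196)  # T-1, T1, T2
    q_completed: tuple[int, int, int] = (394, 270, 313)  # T0, T1, T2 questionnaires

    def own_brand_product_share(self) -> float:
        return share_pct(self.products_own_brand, self.products_total)

    def own_brand_purchase_share(self) -> float:
        return share_pct(self.purchases_own_brand, self.purchases_total)

    def complete_data_rate(self) -> float:
        return share_pct(self.n_complete_data, self.n_recruited, decimals=0)

    def missing_rates(self) -> tuple[float, float, float]:
        return tuple(share_pct(k, self.n_recruited) for k in self.missing_by_period)


REFERENCE = ReferenceCounts()
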