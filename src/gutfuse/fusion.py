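"""Naive-Bayes fusion of the microbiota- and metabolite-channel posteriors.

The two channels are built from disjoint measurements, so their
posteriors are combined under conditional independence given the class:
posterior odds = prior odds x odds(p_m) x odds(p_c).  A channel that is
exactly certain (p = 0 or 1) dominates; two contradictory certainties
have no defined posterior and raise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .plsda import ChannelPosterior

_CLIP = 1e-12


@dataclass
class FusedPosterior:
    sample_id: str
    p_m: float
    p_c: float
    p_fused: float
    assigned_group: str
    confidence: float  # posterior probability of the assigned class

    def __post_init__(self) -> None:
        if self.assigned_group not in ("IBS", "HLT"):
            raise ValueError(f"bad group {self.assigned_group!r}")


def fuse_posteriors(p_m: float, p_c: float, prior_ibs: float = 0.5) -> float:
    """Combine two channel posteriors by the odds product rule."""
    for name, p in (("p_m", p_m), ("p_c", p_c), ("prior_ibs", prior_ibs)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    certain_m = p_m in (0.0, 1.0)
    certain_c = p_c in (0.0, 1.0)
    if certain_m and certain_c and p_m != p_c:
        raise ValueError(
            f"contradictory certainty (p_m={p_m}, p_c={p_c}): posterior undefined"
        )
    if certain_m:
        return float(p_m)
    if certain_c:
        return float(p_c)
    pm = min(max(p_m, _CLIP), 1.0 - _CLIP)
    pc = min(max(p_c, _CLIP), 1.0 - _CLIP)
    pr = min(max(prior_ibs, _CLIP), 1.0 - _CLIP)
    r = (pr / (1.0 - pr)) * (pm / (1.0 - pm)) * (pc / (1.0 - pc))
    return float(r / (1.0 + r))


def fuse_cohort(
    channel_m: list[ChannelPosterior],
    channel_c: list[ChannelPosterior],
    prior_ibs: float = 0.5,
) -> list[FusedPosterior]:
    """Element-wise fusion over a cohort; sample id sets must match.

    Output follows channel_m's sample order.
    """
    by_id_c = {cp.sample_id: cp for cp in channel_c}
    ids_m = [cp.sample_id for cp in channel_m]
    if set(ids_m) != set(by_id_c) or len(ids_m) != len(channel_m):
        raise ValueError("sample id sets differ between the two channels")
    out = []
    for cp in channel_m:
        p = fuse_posteriors(cp.p_ibs, by_id_c[cp.sample_id].p_ibs, prior_ibs)
        group = "IBS" if p >= 0.5 else "HLT"
        out.append(FusedPosterior(cp.sample_id, cp.p_ibs,
                                  by_id_c[cp.sample_id].p_ibs, p, group,
                                  max(p, 1.0 - p)))
    return out
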