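"""Permutation tests for global-latency and relative-phase stimulus effects.

Two families of label-permutation tests operate on the decoder-sequence
fit:

* **latency tests** (H_I: size, H_II: animacy) ask whether the onset time
  of each decoder (state) differs between stimulus classes — evidence of a
  *global* difference in processing speed;
* **PLF tests** (H_III: size, H_IV: animacy) ask whether, within the
  data-driven time window where each decoder is active, phase is more
  consistent within class than across classes — evidence of *relative*
  cross-channel phase configurations over and above latency.

Subject-level tests are combined into group-level p-values with the
non-parametric combination (NPC) algorithm using Fisher's combining
function on synchronized permutation ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phase import plf, decoder_aligned_phases

__all__ = [
    "PermutationOutcome",
    "GroupResult",
    "latency_perm_test",
    "plf_class_perm_test",
    "npc_combine",
    "run_hypothesis_battery",
    "pvalue_quantile_bands",
]


@dataclass
class PermutationOutcome:
    observed: float
    null: np.ndarray  # (n_perm,)
    p: float
    n_perm: int
    seed: int
    test_id: str = ""

    def __post_init__(self) -> None:
        assert len(self.null) == self.n_perm
        assert 0 < self.p <= 1


@dataclass
class GroupResult:
    subject_p: np.ndarray
    group_p: float
    combining: str = "fisher"


def _perm_pvalue(observed: float, null: np.ndarray) -> float:
    """(1 + #{null >= observed}) / (1 + n_perm): never exactly zero."""
    return float((1 + np.sum(null >= observed)) / (1 + len(null)))


def _permuted_masks(mask: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    out = np.tile(mask, (n_perm, 1))
    return rng.permuted(out, axis=1)


def latency_perm_test(
    onsets: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    two_sided: bool = True,
    test_id: str = "",
) -> PermutationOutcome:
    """Label-permutation test on the between-class difference in onset time.

    ``onsets``: per-trial onset of one state, in samples (NaN = state never
    activated; such trials are dropped). The statistic is the (absolute,
    when ``two_sided``) difference of class mean onsets; the null permutes
    the class labels over trials.
    """
    onsets = np.asarray(onsets, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(onsets)
    onsets, labels = onsets[keep], labels[keep]
    classes = np.unique(labels)
    if len(classes) != 2 or min((labels == c).sum() for c in classes) < 1:
        raise ValueError("both classes must be present among valid onsets")
    rng = np.random.default_rng(seed)
    a = labels == classes[0]
    na, nb = int(a.sum()), int((~a).sum())

    def stat(mask_a: np.ndarray) -> np.ndarray:
        ma = mask_a @ onsets / na
        mb = (1 - mask_a) @ onsets / nb
        d = ma - mb
        return np.abs(d) if two_sided else d

    observed = float(stat(a[None, :].astype(float))[0])
    null = stat(_permuted_masks(a.astype(float), n_perm, rng))
    return PermutationOutcome(
        observed=observed, null=null, p=_perm_pvalue(observed, null),
        n_perm=n_perm, seed=seed, test_id=test_id,
    )


def plf_class_perm_test(
    aligned_phases: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    reduce_window: str = "sum",
    min_per_class: int = 3,
    spatial_reference: bool = True,
    test_id: str = "",
) -> PermutationOutcome:
    """Within-class versus pooled phase locking in a decoder window.

    ``aligned_phases``: (N, C, L) phases in a decoder-aligned window. The
    base statistic is sum over channels and window positions of
    PLF(class A) + PLF(class B); it is maximal when within-class locking
    dominates between-class locking. The null permutes class labels.
    ``reduce_window='mean'`` averages over the window instead of summing.

    With ``spatial_reference`` (default) each trial's phases are referenced
    to their spatial circular mean at every window position, so the
    statistic sees only the *relative* cross-channel phase configuration: a
    phase rotation common to all channels — a residual global latency the
    realignment did not fully remove — cancels exactly, which is what a
    test for relative (as opposed to global) phase structure requires.
    """
    ph = np.asarray(aligned_phases, dtype=float)
    if spatial_reference and ph.shape[1] > 1:
        spatial_mean = np.angle(np.exp(1j * ph).mean(axis=1, keepdims=True))
        ph = ph - spatial_mean
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < min_per_class:
        raise ValueError(
            f"class with {min(counts)} trials (< {min_per_class}) in this state window"
        )
    n = ph.shape[0]
    z = np.exp(1j * ph).reshape(n, -1)  # (N, C*L)
    rng = np.random.default_rng(seed)
    a = (labels == classes[0]).astype(float)
    na, nb = a.sum(), n - a.sum()

    def stat(mask_a: np.ndarray) -> np.ndarray:
        sa = np.abs(mask_a @ z) / na
        sb = np.abs((1 - mask_a) @ z) / nb
        s = sa + sb
        return s.sum(axis=1) if reduce_window == "sum" else s.mean(axis=1)

    observed = float(stat(a[None, :])[0])
    null = stat(_permuted_masks(a, n_perm, rng))
    return PermutationOutcome(
        observed=observed, null=null, p=_perm_pvalue(observed, null),
        n_perm=n_perm, seed=seed, test_id=test_id,
    )


def npc_combine(outcomes: list[PermutationOutcome], combining: str = "fisher") -> GroupResult:
    """Non-parametric combination of synchronized permutation tests.

    For permutation r of each unit (subject/test), the partial p is the rank
    of that permutation's statistic within the unit's own pooled sample
    (observed + null); Fisher's function -2*sum(log p) combines units, and
    the group p is the proportion of permutations whose combined value
    meets or exceeds the observed one (with the +1 correction).
    """
    if not outcomes:
        raise ValueError("no outcomes to combine")
    n_perm = outcomes[0].n_perm
    if any(o.n_perm != n_perm for o in outcomes):
        raise ValueError("all units must share the same n_perm")
    n_tot = n_perm + 1
    logp = np.zeros((len(outcomes), n_tot))
    for i, o in enumerate(outcomes):
        vals = np.concatenate([[o.observed], o.null])  # index 0 = observed
        # p-hat of each value: proportion of pooled values >= it
        # (ties share the larger, more conservative rank)
        srt = np.sort(vals)
        ranks = n_tot - np.searchsorted(srt, vals, side="left")
        logp[i] = np.log(ranks / n_tot)
    combined = -2 * logp.sum(axis=0)
    group_p = float((1 + np.sum(combined[1:] >= combined[0])) / n_tot)
    return GroupResult(
        subject_p=np.array([o.p for o in outcomes]), group_p=group_p, combining=combining
    )


def pvalue_quantile_bands(pvals: np.ndarray) -> dict[str, float]:
    """Central quantile bands (50/75/87.5/95%) of a p-value collection."""
    p = np.asarray(pvals, dtype=float)
    out = {"median": float(np.median(p))}
    for cover in (50, 75, 87.5, 95):
        half = cover / 200.0
        out[f"band{cover}_lo"] = float(np.quantile(p, 0.5 - half))
        out[f"band{cover}_hi"] = float(np.quantile(p, 0.5 + half))
    return out


_HYPOTHESES = {  # (name, attribute, family)
    "H_I": ("size", "latency"),
    "H_II": ("animacy", "latency"),
    "H_III": ("size", "plf"),
    "H_IV": ("animacy", "plf"),
}


def run_hypothesis_battery(
    subjects: list[dict],
    n_perm: int = 1000,
    seed: int = 0,
    resample_len: int = 10,
    hypotheses: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run H_I–H_IV for every subject, state and category pair, plus NPC
    group-level p-values per state.

    Each subject dict needs: ``gamma`` (T, N, K) from the decoder-sequence
    fit, ``phases`` (N, C, T) instantaneous phases of the oscillatory
    component, and ``attributes`` mapping 'animacy'/'size' to per-trial
    values. Latency hypotheses are tested for states 2..K; PLF hypotheses
    for all states. Returns (per-test table, group table).
    """
    rng = np.random.default_rng(seed)
    if hypotheses is None:
        hypotheses = list(_HYPOTHESES)
    rows = []
    units: dict[tuple, list[PermutationOutcome]] = {}
    for s, sub in enumerate(subjects):
        gamma = sub["gamma"]
        K = gamma.shape[2]
        onsets = state_onsets_cached(sub)
        for hyp in hypotheses:
            attr, family = _HYPOTHESES[hyp]
            values = np.asarray(sub["attributes"][attr])
            levels = np.unique(values)
            pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
            for va, vb in pairs:
                sel = (values == va) | (values == vb)
                states = range(1, K) if family == "latency" else range(K)
                for k in states:
                    test_seed = int(rng.integers(2**31 - 1))
                    tid = f"{hyp}/s{s}/state{k + 1}/{va}v{vb}"
                    try:
                        if family == "latency":
                            out = latency_perm_test(
                                onsets[sel, k - 1], values[sel], n_perm=n_perm,
                                seed=test_seed, test_id=tid,
                            )
                        else:
                            aligned, included = decoder_aligned_phases(
                                sub["phases"], gamma, k, resample_len
                            )
                            lab = values[included]
                            pick = (lab == va) | (lab == vb)
                            out = plf_class_perm_test(
                                aligned[pick], lab[pick], n_perm=n_perm,
                                seed=test_seed, test_id=tid,
                            )
                    except ValueError:
                        continue  # state skipped (missing class / too few trials)
                    rows.append({
                        "hypothesis": hyp, "subject": s, "state": k + 1,
                        "pair": f"{va}v{vb}", "statistic": out.observed,
                        "p": out.p, "n_perm": n_perm, "seed": test_seed,
                    })
                    units.setdefault((hyp, k + 1), []).append(out)

    table = pd.DataFrame(rows)
    group_rows = []
    for (hyp, state), outs in sorted(units.items()):
        res = npc_combine(outs)
        group_rows.append({
            "hypothesis": hyp, "state": state, "n_units": len(outs),
            "group_p": res.group_p,
        })
    return table, pd.DataFrame(group_rows)


def state_onsets_cached(sub: dict) -> np.ndarray:
    from .tuda import state_onsets

    if "onsets" not in sub:
        sub["onsets"] = state_onsets(sub["gamma"])
    return sub["onsets"]
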