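"""Synthetic taxonomy-annotated databases and community profiles with
planted ground truth.

Every pipeline stage is testable without downloading reference databases:

* :func:`generate_reference_db` builds rDNA-operon-like records — a 16S
  tail flank, a forward primer site mutated at an exact planted mismatch
  count, a variable-length intergenic spacer, the reverse-complemented
  reverse site mutated likewise, and a 23S head flank — over a
  hierarchical taxonomy, and returns the analytic ground truth.
* :func:`generate_nontarget_db` builds chloroplast-, plant- or
  fungal-like records that verifiably carry no binding site (or, for a
  controlled contamination fraction, degenerate planted sites).
* :func:`generate_community_profiles` draws two-group ARISA fingerprints
  with a tunable compositional effect.
* :func:`simulate_fingerprint_from_db` links the two halves: a community
  abundance vector plus a virtual-PCR hit table yields the fingerprint a
  capillary run of that community would produce, primer dropout included.

Planted mismatches are placed only at primer positions whose degenerate
code does not already accept every base, and the substituted base is
drawn from outside the code's set — the mismatch count is exact, not
probabilistic.  Flanks and spacers are rejection-resampled until a
verification scan at mismatch budget 3 (both strands, all primer sets in
the plan) finds exactly the planted sites and nothing else, so ground
truth is exact by construction.  All randomness flows from one master
seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .community import Fingerprint
from .coverage import RANKS, Lineage
from .pcr import (
    DEFAULT_LENGTH_BOUNDS,
    AmplificationResult,
    ReferenceRecord,
    encode_iupac,
    mismatch_profile,
)
from .primers import IUPAC_SETS, PrimerSet, reverse_complement

__all__ = [
    "DbSpec",
    "GroundTruth",
    "CommunitySpec",
    "InfeasibleSpecError",
    "generate_reference_db",
    "generate_nontarget_db",
    "generate_community_profiles",
    "simulate_fingerprint_from_db",
    "NONTARGET_PHYLA",
]

_BASES = "ACGT"
_VERIFY_BUDGET = 3  # spurious sites are excluded up to this budget


class InfeasibleSpecError(ValueError):
    """The requested planting cannot be realized (e.g. more mismatches than
    mutable primer positions, or mutually cross-matching primer sets)."""


@dataclass(frozen=True)
class DbSpec:
    """Parameters of a synthetic reference database.

    ``site_plans`` maps a primer-set name to the fraction of species whose
    operon carries a binding site at exactly 0/1/2/3 mismatches (on both
    primers); the remainder of species carry no site for that set.
    Fractions are realized as exact counts (largest-remainder rounding).
    """

    n_species: int = 200
    n_phyla: int = 5
    classes_per_phylum: int = 2
    orders_per_class: int = 2
    families_per_order: int = 2
    genera_per_family: int = 3
    site_plans: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {"default": {0: 1.0}}
    )
    igs_length_range: tuple[int, int] = (100, 1400)
    igs_lengths: Sequence[int] | None = None
    flank_length: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        for n, what in [
            (self.n_species, "n_species"), (self.n_phyla, "n_phyla"),
            (self.classes_per_phylum, "classes_per_phylum"),
            (self.orders_per_class, "orders_per_class"),
            (self.families_per_order, "families_per_order"),
            (self.genera_per_family, "genera_per_family"),
        ]:
            if n < 1:
                raise ValueError(f"{what} must be >= 1")
        for set_name, plan in self.site_plans.items():
            tot = 0.0
            for mm, frac in plan.items():
                if mm not in (0, 1, 2, 3):
                    raise ValueError(f"planted mismatch count must be 0..3, got {mm}")
                if frac < 0:
                    raise ValueError("plan fractions must be >= 0")
                tot += frac
            if tot > 1 + 1e-9:
                raise ValueError(
                    f"plan fractions for {set_name!r} sum to {tot} > 1"
                )
        if self.flank_length < 1:
            raise ValueError("flank_length must be >= 1")


@dataclass
class GroundTruth:
    """Analytic planted truth for a generated database.

    ``table`` has one row per record x primer set with the planted
    forward/reverse mismatch counts and product lengths (``planted``
    False and NaN lengths for species carrying no site).  All derived
    quantities here are computed from the plan alone, independently of
    the virtual-PCR engine.
    """

    table: pd.DataFrame
    taxonomy: dict[str, Lineage]

    def amplified_record_ids(self, primer_set: str, budget: int) -> set[str]:
        t = self.table
        sel = (
            (t["primer_set"] == primer_set)
            & t["planted"]
            & (t["fwd_mismatches"] <= budget)
            & (t["rev_mismatches"] <= budget)
        )
        return set(t.loc[sel, "record_id"])

    def coverage_table(
        self,
        primer_set: str,
        budgets: Sequence[int],
        ranks: Sequence[str] = RANKS,
    ) -> pd.DataFrame:
        """Rank x budget coverage the pipeline must reproduce exactly."""
        denom: dict[str, set] = {r: set() for r in ranks}
        for lin in self.taxonomy.values():
            for r in ranks:
                p = lin.path(r)
                if p is not None:
                    denom[r].add(p)
        rows = []
        for b in sorted(budgets):
            ids = self.amplified_record_ids(primer_set, b)
            for r in ranks:
                amped = {
                    self.taxonomy[i].path(r)
                    for i in ids
                    if self.taxonomy[i].path(r) is not None
                }
                total = len(denom[r])
                rows.append(
                    {
                        "primer_set": primer_set,
                        "rank": r,
                        "budget": b,
                        "n_taxa_total": total,
                        "n_taxa_amplified": len(amped),
                        "proportion": 100.0 * len(amped) / total if total else float("nan"),
                    }
                )
        return pd.DataFrame(rows)

    def phylum_species_counts(
        self, primer_set: str, budgets: Sequence[int]
    ) -> pd.DataFrame:
        """Phylum x budget distinct-species counts with totals."""
        species_total: dict[str, set] = {}
        for lin in self.taxonomy.values():
            sp = lin.path("species")
            if sp is not None:
                species_total.setdefault(sp[0], set()).add(sp)
        phyla = sorted(species_total)
        budgets = sorted(budgets)
        mat = pd.DataFrame(0, index=pd.Index(phyla, name="phylum"), columns=budgets)
        for b in budgets:
            for rid in self.amplified_record_ids(primer_set, b):
                sp = self.taxonomy[rid].path("species")
                if sp is not None:
                    mat.loc[sp[0], b] += 1
        mat["species_total"] = [len(species_total[p]) for p in phyla]
        return mat


# ---------------------------------------------------------------------------
# sequence assembly


def _substream(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _concrete_site(primer_seq: str, n_mismatch: int, rng: np.random.Generator) -> str:
    """A concrete ACGT window binding the primer at exactly ``n_mismatch``.

    Mismatch positions are drawn uniformly among primer positions whose
    IUPAC code does not accept every base; the substituted base is drawn
    from outside the code's set, guaranteeing the count.
    """
    sets = [IUPAC_SETS[c] for c in primer_seq]
    mutable = [i for i, s in enumerate(sets) if len(s) < 4]
    if n_mismatch > len(mutable):
        raise InfeasibleSpecError(
            f"cannot plant {n_mismatch} mismatches: primer has only "
            f"{len(mutable)} non-N positions"
        )
    mm_pos = set(
        int(mutable[i]) for i in rng.choice(len(mutable), size=n_mismatch, replace=False)
    ) if n_mismatch else set()
    out = []
    for i, s in enumerate(sets):
        pool = sorted(set(_BASES) - s) if i in mm_pos else sorted(s)
        out.append(pool[int(rng.integers(0, len(pool)))])
    return "".join(out)


def _scan_starts(seq_masks: np.ndarray, primer_seq: str, budget: int) -> set[int]:
    counts = mismatch_profile(seq_masks, encode_iupac(primer_seq))
    return set(int(i) for i in np.flatnonzero(counts <= budget))


def _assemble_record(
    record_id: str,
    planted: Mapping[str, tuple[int, int]],
    primer_sets: Mapping[str, PrimerSet],
    igs_length: int,
    flank_length: int,
    rng: np.random.Generator,
    max_tries: int = 60,
) -> tuple[str, dict[str, dict[str, int]]]:
    """Assemble one operon-like record and verify the planted truth.

    ``planted`` maps primer-set name -> (fwd_mm, rev_mm) for the sets
    carried by this record.  Forward sites are laid left-to-right in set
    order before the spacer; reverse-complemented reverse sites follow it
    in the opposite order, so every planted pair is properly nested.
    Returns the sequence and, per planted set, the exact site coordinates
    and product lengths.  Flanks/spacer are resampled until a budget-3
    scan for every primer (and its reverse complement, covering the
    - strand) finds exactly the planted sites.
    """
    order = [name for name in primer_sets if name in planted]
    for _ in range(max_tries):
        fwd_sites = {n: _concrete_site(primer_sets[n].forward.sequence, planted[n][0], rng)
                     for n in order}
        rev_sites = {n: _concrete_site(primer_sets[n].reverse.sequence, planted[n][1], rng)
                     for n in order}
        parts: list[str] = [_random_dna(rng, flank_length)]
        pos = flank_length
        fwd_at: dict[str, int] = {}
        rev_rc_at: dict[str, int] = {}
        for n in order:
            fwd_at[n] = pos
            parts.append(fwd_sites[n])
            pos += len(fwd_sites[n])
        parts.append(_random_dna(rng, igs_length))
        pos += igs_length
        for n in reversed(order):
            rc = reverse_complement(rev_sites[n])
            rev_rc_at[n] = pos
            parts.append(rc)
            pos += len(rc)
        parts.append(_random_dna(rng, flank_length))
        seq = "".join(parts)

        masks = encode_iupac(seq)
        rc_masks = encode_iupac(reverse_complement(seq))
        ok = True
        for name, pset in primer_sets.items():
            f = pset.forward.sequence
            r_rc = reverse_complement(pset.reverse.sequence)
            r = pset.reverse.sequence
            f_rc = reverse_complement(f)
            exp_f = {fwd_at[name]} if name in planted else set()
            exp_r = {rev_rc_at[name]} if name in planted else set()
            if _scan_starts(masks, f, _VERIFY_BUDGET) != exp_f:
                ok = False
            elif _scan_starts(masks, r_rc, _VERIFY_BUDGET) != exp_r:
                ok = False
            # no sites on the - strand: the engine searches both
            elif _scan_starts(rc_masks, f, _VERIFY_BUDGET):
                ok = False
            elif _scan_starts(rc_masks, r_rc, _VERIFY_BUDGET):
                ok = False
            if not ok:
                break
        if not ok:
            continue
        truth: dict[str, dict[str, int]] = {}
        for n in order:
            flen = len(primer_sets[n].forward.sequence)
            rlen = len(primer_sets[n].reverse.sequence)
            fwd_end = fwd_at[n] + flen
            rev_end = rev_rc_at[n] + rlen
            truth[n] = {
                "fwd_start": fwd_at[n],
                "rev_start": rev_rc_at[n],
                "inner_length": rev_rc_at[n] - fwd_end,
                "full_length": rev_end - fwd_at[n],
            }
        return seq, truth
    raise InfeasibleSpecError(
        f"could not assemble record {record_id} free of spurious sites after "
        f"{max_tries} attempts; the primer sets in the plan likely cross-match"
    )


def _largest_remainder_counts(fractions: Mapping[int, float], n: int) -> dict[int, int]:
    """Exact integer counts per category from fractions of n."""
    items = sorted(fractions.items())
    raw = {k: f * n for k, f in items}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = int(round(sum(raw.values()))) - sum(counts.values())
    order = sorted(items, key=lambda kv: raw[kv[0]] - counts[kv[0]], reverse=True)
    for k, _ in order[:short]:
        counts[k] += 1
    return counts


def _build_taxonomy(spec: DbSpec) -> dict[str, Lineage]:
    """Round-robin the species over a fixed branching-factor tree."""
    genera: list[tuple[str, ...]] = []
    for p in range(spec.n_phyla):
        ph = f"Phylum{p + 1:02d}"
        for c in range(spec.classes_per_phylum):
            cl = f"{ph}.c{c + 1}"
            for o in range(spec.orders_per_class):
                od = f"{cl}.o{o + 1}"
                for f in range(spec.families_per_order):
                    fa = f"{od}.f{f + 1}"
                    for g in range(spec.genera_per_family):
                        genera.append((ph, cl, od, fa, f"{fa}.g{g + 1}"))
    taxonomy: dict[str, Lineage] = {}
    for i in range(spec.n_species):
        path = genera[i % len(genera)]
        rid = f"sp{i + 1:04d}"
        taxonomy[rid] = Lineage(*path, f"{path[-1]}.{rid}")
    return taxonomy


def generate_reference_db(
    spec: DbSpec, primer_sets: Mapping[str, PrimerSet]
) -> tuple[list[ReferenceRecord], dict[str, Lineage], GroundTruth]:
    """Generate an operon-like reference database with exact planted truth.

    One record per species.  Deterministic given ``spec.seed``: the same
    spec yields byte-identical sequences.
    """
    missing = set(spec.site_plans) - set(primer_sets)
    if missing:
        raise ValueError(f"site_plans reference unknown primer sets: {sorted(missing)}")
    taxonomy = _build_taxonomy(spec)
    record_ids = sorted(taxonomy)

    # per primer set: assign each species a planted mismatch count (or absence)
    assign: dict[str, dict[str, int]] = {}
    for k, (set_name, plan) in enumerate(sorted(spec.site_plans.items())):
        counts = _largest_remainder_counts(plan, spec.n_species)
        rng_assign = _substream(spec.seed, 1, k)
        perm = rng_assign.permutation(spec.n_species)
        per_record: dict[str, int] = {}
        pos = 0
        for mm in sorted(counts):
            for idx in perm[pos : pos + counts[mm]]:
                per_record[record_ids[int(idx)]] = mm
            pos += counts[mm]
        assign[set_name] = per_record

    rng_igs = _substream(spec.seed, 2)
    if spec.igs_lengths is not None:
        igs = [int(spec.igs_lengths[i % len(spec.igs_lengths)]) for i in range(spec.n_species)]
    else:
        lo, hi = spec.igs_length_range
        igs = [int(x) for x in rng_igs.integers(lo, hi + 1, size=spec.n_species)]

    used_sets = {n: primer_sets[n] for n in sorted(spec.site_plans)}
    records: list[ReferenceRecord] = []
    rows = []
    for i, rid in enumerate(record_ids):
        planted = {
            n: (assign[n][rid], assign[n][rid]) for n in used_sets if rid in assign[n]
        }
        rng_rec = _substream(spec.seed, 3, i)
        seq, truth = _assemble_record(
            rid, planted, used_sets, igs[i], spec.flank_length, rng_rec
        )
        records.append(ReferenceRecord(rid, seq, taxonomy[rid]))
        for n in used_sets:
            if n in truth:
                rows.append(
                    {
                        "record_id": rid, "primer_set": n, "planted": True,
                        "fwd_mismatches": planted[n][0], "rev_mismatches": planted[n][1],
                        "inner_length": truth[n]["inner_length"],
                        "full_length": truth[n]["full_length"],
                    }
                )
            else:
                rows.append(
                    {
                        "record_id": rid, "primer_set": n, "planted": False,
                        "fwd_mismatches": np.nan, "rev_mismatches": np.nan,
                        "inner_length": np.nan, "full_length": np.nan,
                    }
                )
    truth_table = pd.DataFrame(rows)
    return records, taxonomy, GroundTruth(truth_table, taxonomy)


#: Phylum namespaces used for the emulated non-target databases; drawn
#: from a non-bacterial namespace so reports never collide with the
#: bacterial taxonomy.
NONTARGET_PHYLA: Mapping[str, tuple[str, ...]] = {
    "chloroplast-like": ("Chlorophyta", "Chromerida", "Euglenida"),
    "plant-like": ("Streptophyta", "Chlorophyta"),
    "fungal-like": ("Ascomycota", "Basidiomycota", "Mucoromycota"),
}


def generate_nontarget_db(
    kind: str,
    primer_sets: Mapping[str, PrimerSet],
    n_species: int = 100,
    contamination_fraction: float = 0.0,
    planted_mismatches: int = 0,
    igs_length_range: tuple[int, int] = (100, 1400),
    flank_length: int = 80,
    seed: int = 0,
) -> tuple[list[ReferenceRecord], dict[str, Lineage], GroundTruth]:
    """Generate a non-target (chloroplast/plant/fungal-like) database.

    A fraction ``contamination_fraction`` of species (an exact count,
    nearest-integer) degenerately carry binding sites for every primer
    set at ``planted_mismatches`` mismatches — emulating the handful of
    amplifiable algal/plant entries real screens turn up; the rest
    verifiably carry no site within mismatch budget 3.
    """
    if kind not in NONTARGET_PHYLA:
        raise ValueError(f"kind must be one of {sorted(NONTARGET_PHYLA)}, got {kind!r}")
    if not 0 <= contamination_fraction <= 1:
        raise ValueError("contamination_fraction must be in [0, 1]")
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    phyla = NONTARGET_PHYLA[kind]
    prefix = {"chloroplast-like": "chl", "plant-like": "pln", "fungal-like": "fun"}[kind]
    taxonomy: dict[str, Lineage] = {}
    record_ids = []
    for i in range(n_species):
        ph = phyla[i % len(phyla)]
        rid = f"{prefix}{i + 1:04d}"
        record_ids.append(rid)
        taxonomy[rid] = Lineage(
            ph, f"{ph}.c1", f"{ph}.c1.o1", f"{ph}.c1.o1.f1",
            f"{ph}.c1.o1.f1.g{i % 7 + 1}", f"{ph}.{rid}",
        )

    n_contam = int(round(contamination_fraction * n_species))
    rng_pick = _substream(seed, 11)
    contaminated = set(
        record_ids[int(i)] for i in rng_pick.choice(n_species, size=n_contam, replace=False)
    )

    used_sets = dict(primer_sets)
    rng_igs = _substream(seed, 12)
    lo, hi = igs_length_range
    records: list[ReferenceRecord] = []
    rows = []
    for i, rid in enumerate(record_ids):
        igs = int(rng_igs.integers(lo, hi + 1))
        rng_rec = _substream(seed, 13, i)
        if rid in contaminated:
            planted = {n: (planted_mismatches, planted_mismatches) for n in used_sets}
        else:
            planted = {}
        seq, truth = _assemble_record(rid, planted, used_sets, igs, flank_length, rng_rec)
        records.append(ReferenceRecord(rid, seq, taxonomy[rid]))
        for n in used_sets:
            if n in truth:
                rows.append(
                    {
                        "record_id": rid, "primer_set": n, "planted": True,
                        "fwd_mismatches": planted_mismatches,
                        "rev_mismatches": planted_mismatches,
                        "inner_length": truth[n]["inner_length"],
                        "full_length": truth[n]["full_length"],
                    }
                )
            else:
                rows.append(
                    {
                        "record_id": rid, "primer_set": n, "planted": False,
                        "fwd_mismatches": np.nan, "rev_mismatches": np.nan,
                        "inner_length": np.nan, "full_length": np.nan,
                    }
                )
    return records, taxonomy, GroundTruth(pd.DataFrame(rows), taxonomy)


@dataclass(frozen=True)
class CommunitySpec:
    """A two-group community design for ARISA fingerprint simulation.

    Defaults mirror a typical paired field design: two treatment groups
    of five replicate samples each, an OTU pool of 100 fragment-length
    classes of which 70% are shared between groups, log-normal
    abundances, and a multiplicative compositional group effect.
    """

    group_labels: tuple[str, str] = ("group_a", "group_b")
    n_per_group: int = 5
    pool_size: int = 100
    shared_fraction: float = 0.7
    effect_size: float = 1.0
    lognormal_mu: float = 3.0
    lognormal_sigma: float = 1.0
    noise_sigma: float = 0.3
    presence_prob: float = 0.9
    fragment_range: tuple[float, float] = (100.0, 1500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.presence_prob <= 1:
            raise ValueError("presence_prob must be in (0, 1]")


def generate_community_profiles(
    spec: CommunitySpec,
) -> tuple[list[Fingerprint], dict[str, str]]:
    """Draw per-sample fingerprints for a two-group design.

    Each OTU is a fragment length drawn once (fractional, capillary-like)
    from ``fragment_range``.  Both groups share ``shared_fraction`` of the
    pool; the remainder is split into group-exclusive OTUs.  Per-sample
    abundances are log-normal around a per-OTU mean shifted by
    ``effect_size`` in opposite directions for the two groups, with
    multiplicative noise and Bernoulli per-sample occupancy.
    Deterministic given ``spec.seed``.
    """
    rng_pool = _substream(spec.seed, 21)
    lengths = rng_pool.uniform(*spec.fragment_range, size=spec.pool_size)
    mu = rng_pool.normal(spec.lognormal_mu, spec.lognormal_sigma, size=spec.pool_size)
    delta = rng_pool.normal(0.0, 1.0, size=spec.pool_size)

    n_shared = int(round(spec.shared_fraction * spec.pool_size))
    n_excl = spec.pool_size - n_shared
    n_a = n_excl // 2
    members = {
        spec.group_labels[0]: np.r_[np.arange(n_shared), n_shared + np.arange(n_a)],
        spec.group_labels[1]: np.r_[np.arange(n_shared), n_shared + n_a + np.arange(n_excl - n_a)],
    }
    sign = {spec.group_labels[0]: +0.5, spec.group_labels[1]: -0.5}

    fingerprints: list[Fingerprint] = []
    groups: dict[str, str] = {}
    rng_s = _substream(spec.seed, 22)
    for g in spec.group_labels:
        idx = members[g]
        for k in range(spec.n_per_group):
            sid = f"{g}_{k + 1}"
            present = rng_s.random(idx.size) < spec.presence_prob
            eps = rng_s.normal(0.0, spec.noise_sigma, size=idx.size)
            logab = mu[idx] + sign[g] * spec.effect_size * delta[idx] + eps
            peaks = [
                (float(lengths[i]), float(np.exp(la)))
                for i, la, keep in zip(idx, logab, present)
                if keep
            ]
            fingerprints.append(Fingerprint(sid, peaks))
            groups[sid] = g
    return fingerprints, groups


def simulate_fingerprint_from_db(
    result: AmplificationResult,
    community: Mapping[str, float],
    sample_id: str = "sample",
) -> Fingerprint:
    """Fingerprint of a community under one assay's virtual amplification.

    Each community member that amplified contributes a peak at its primary
    amplicon's full product length with the member's abundance; members
    that did not amplify contribute nothing (primer-bias dropout).  Peaks
    at identical lengths are summed.
    """
    primary = result.primary_amplicons()
    peaks: dict[float, float] = {}
    for rid, abundance in community.items():
        if abundance < 0:
            raise ValueError(f"negative abundance for {rid}")
        amp = primary.get(rid)
        if amp is None or abundance == 0:
            continue
        length = float(amp.full_length)
        peaks[length] = peaks.get(length, 0.0) + float(abundance)
    return Fingerprint(sample_id, sorted(peaks.items()))
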