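"""emPAI-based label-free molar quantification of digestive proteomes.

The exponentially modified protein abundance index,

    emPAI = 10^(observed / observable) - 1,

is proportional to a protein's molar amount: ``observed`` is the number of
distinct tryptic peptides identified for the protein and ``observable`` the
number of its fully tryptic peptides whose monoisotopic mass falls inside the
instrument's detectable window.  Molar percentages are emPAI shares within a
(compartment, replicate) group.  Identification evidence is filtered the way
the source search results were: peptide matches must have expect <= 0.05, and
proteins need at least two distinct surviving peptides (in at least one sample
for organ comparisons).
"""

from __future__ import annotations

import warnings

import pandas as pd
from pyteomics import mass as _pymass
from pyteomics import parser as _pyparser

__all__ = [
    "VALID_RESIDUES",
    "DEFAULT_MASS_WINDOW",
    "CARBAMIDOMETHYL_MASS",
    "tryptic_digest",
    "peptide_mass",
    "observable_peptides",
    "empai",
    "filter_identifications",
    "quantify",
    "molar_percentages",
    "normalize_replicates",
    "family_summary",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

PROTON_MASS = 1.00728  # Da
#: fixed carbamidomethylation of cysteine, matching the search settings
CARBAMIDOMETHYL_MASS = 57.02146
#: neutral monoisotopic mass window implied by m/z 375-1500 at charges 2-5
DEFAULT_MASS_WINDOW = (375.0 * 2 - 2 * PROTON_MASS, 1500.0 * 5 - 5 * PROTON_MASS)

_TRYPSIN_RULE = _pyparser.expasy_rules["trypsin"]  # cleave after K/R, not before P


def _validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty protein sequence")
    for i, residue in enumerate(seq):
        if residue not in VALID_RESIDUES:
            raise ValueError(f"invalid residue {residue!r} at position {i + 1}")
    return seq


def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """In-silico trypsin digest: cleave C-terminal to K/R except before P.

    Returns the unique peptides with up to ``missed_cleavages`` internal
    sites, in order of first appearance in the protein.
    """
    seq = _validate_sequence(sequence)
    if not 0 <= missed_cleavages:
        raise ValueError("missed_cleavages must be >= 0")
    pieces = _pyparser.xcleave(seq, _TRYPSIN_RULE, missed_cleavages=missed_cleavages)
    pieces.sort(key=lambda t: (t[0], len(t[1])))
    seen: dict[str, None] = {}
    for _, pep in pieces:
        seen.setdefault(pep, None)
    return list(seen)


def peptide_mass(peptide: str) -> float:
    """Monoisotopic peptide mass (Da) with fixed carbamidomethyl-C."""
    pep = _validate_sequence(peptide)
    return _pymass.fast_mass(pep) + CARBAMIDOMETHYL_MASS * pep.count("C")


def observable_peptides(
    sequence: str, mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW
) -> int:
    """Count fully tryptic (0 missed cleavages) peptides inside the window."""
    lo, hi = mass_window
    peptides = tryptic_digest(sequence, missed_cleavages=0)
    return sum(1 for p in peptides if lo <= peptide_mass(p) <= hi)


def empai(observed: int, observable: int) -> float:
    """emPAI = 10^(observed/observable) - 1; observed capped at observable."""
    if observable < 1:
        raise ValueError("observable peptide count must be >= 1")
    if observed < 0:
        raise ValueError("observed peptide count must be >= 0")
    if observed > observable:
        warnings.warn(
            f"observed ({observed}) exceeds observable ({observable}); capping",
            stacklevel=2,
        )
        observed = observable
    return 10.0 ** (observed / observable) - 1.0


# ---------------------------------------------------------------------------
# evidence filtering and quantification

EVIDENCE_COLUMNS = ["protein_id", "peptide", "expect", "sample", "compartment", "replicate"]


def filter_identifications(
    matches: pd.DataFrame,
    expect_cutoff: float = 0.05,
    min_peptides: int = 2,
    scope: str = "any_sample",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the expect-score and minimum-peptide identification filters.

    Peptide matches with expect > ``expect_cutoff`` are dropped first.  A
    protein is then retained if it has >= ``min_peptides`` distinct surviving
    peptides -- in at least one sample (``scope="any_sample"``, the
    organ-comparison rule) or pooled over all samples (``scope="global"``, the
    purified-extract rule).  Returns the filtered table and a per-protein
    retention report.  Idempotent: filtering twice equals filtering once.
    """
    if scope not in ("any_sample", "global"):
        raise ValueError("scope must be 'any_sample' or 'global'")
    if matches.empty:
        empty_report = pd.DataFrame(
            columns=["protein_id", "max_unique_peptides", "retained"]
        )
        return matches.copy(), empty_report

    passing = matches[matches["expect"] <= expect_cutoff]
    if scope == "any_sample":
        per_protein = (
            passing.groupby(["protein_id", "sample"])["peptide"]
            .nunique()
            .groupby("protein_id")
            .max()
        )
    else:
        per_protein = passing.groupby("protein_id")["peptide"].nunique()
    # proteins whose every match failed the expect filter count zero peptides
    all_proteins = pd.Index(matches["protein_id"].unique(), name="protein_id")
    per_protein = per_protein.reindex(all_proteins, fill_value=0)
    retained = per_protein[per_protein >= min_peptides].index
    report = pd.DataFrame(
        {
            "protein_id": per_protein.index,
            "max_unique_peptides": per_protein.values,
            "retained": per_protein.values >= min_peptides,
        }
    ).reset_index(drop=True)
    out = passing[passing["protein_id"].isin(retained)].reset_index(drop=True)
    return out, report


def quantify(
    evidence: pd.DataFrame,
    sequences: dict[str, str],
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW,
) -> pd.DataFrame:
    """Per (protein, compartment, replicate) observed/observable counts and emPAI.

    ``sequences`` maps protein id to amino-acid sequence (e.g. parsed from the
    accompanying FASTA); every protein in the evidence must be present.
    """
    missing = set(evidence["protein_id"]) - set(sequences)
    if missing:
        raise KeyError(f"sequences missing for proteins: {sorted(missing)[:5]}")
    observable = {
        pid: observable_peptides(seq, mass_window) for pid, seq in sequences.items()
    }
    zero_obs = [p for p in set(evidence["protein_id"]) if observable[p] == 0]
    if zero_obs:
        raise ValueError(f"proteins with no observable peptides: {sorted(zero_obs)[:5]}")
    grouped = (
        evidence.groupby(["protein_id", "compartment", "replicate"])["peptide"]
        .nunique()
        .rename("observed")
        .reset_index()
    )
    grouped["observable"] = grouped["protein_id"].map(observable)
    grouped["empai"] = [
        empai(min(o, n), n) for o, n in zip(grouped["observed"], grouped["observable"])
    ]
    return grouped


def molar_percentages(
    quants: pd.DataFrame,
    group_cols: tuple[str, ...] = ("compartment", "replicate"),
    value_col: str = "empai",
) -> pd.DataFrame:
    """Add mol_pct = 100 * emPAI / sum(emPAI) within each group.

    Groups with zero total are flagged and excluded from the output.
    """
    out = quants.copy()
    totals = out.groupby(list(group_cols))[value_col].transform("sum")
    zero = totals <= 0
    if zero.any():
        dropped = out.loc[zero, list(group_cols)].drop_duplicates()
        warnings.warn(f"dropping zero-sum groups: {dropped.to_dict('records')}", stacklevel=2)
        out = out[~zero]
        totals = totals[~zero]
    out["mol_pct"] = 100.0 * out[value_col] / totals
    return out.reset_index(drop=True)


def normalize_replicates(
    quants: pd.DataFrame,
    organs: tuple[str, ...],
    value_col: str = "empai",
) -> pd.DataFrame:
    """Scale each replicate so its cross-organ total equals the replicate mean.

    Normalizes intra-sample on the expectation of equal total protein amount
    between replicates when summed across all organs.  Every replicate must
    cover every listed organ.
    """
    out = quants.copy()
    present = out[out["compartment"].isin(organs)]
    cover = present.groupby("replicate")["compartment"].agg(lambda s: set(s))
    for rep, comps in cover.items():
        missing = set(organs) - comps
        if missing:
            raise ValueError(f"replicate {rep} missing organs {sorted(missing)}")
    totals = present.groupby("replicate")[value_col].sum()
    target = totals.mean()
    scale = target / totals
    out[value_col] = out[value_col] * out["replicate"].map(scale)
    return out


def family_summary(
    quants: pd.DataFrame,
    annotations: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GH-family shares among GH proteins, and per-compartment contrasts.

    ``annotations`` maps protein id to a family label ("GH7", "GH9", ...,
    "hemocyanin", "ferritin"); unannotated proteins fall into "other".
    Requires a ``mol_pct`` column (see :func:`molar_percentages`).

    Returns ``(gh_shares, contrasts)``: per (compartment, replicate, family)
    molar share renormalized within the GH subset, and per (compartment,
    family) mean +/- SD of whole-proteome mol% across replicates (the
    hemocyanin fluid-vs-tissue comparison reads from the latter).
    """
    if "mol_pct" not in quants.columns:
        raise ValueError("run molar_percentages first (no mol_pct column)")
    out = quants.copy()
    out["family"] = out["protein_id"].map(lambda p: annotations.get(p, "other"))

    gh = out[out["family"].str.match(r"GH\d+$")]
    if gh.empty:
        warnings.warn("no GH-family proteins in the quant table", stacklevel=2)
        gh_shares = pd.DataFrame(
            columns=["compartment", "replicate", "family", "gh_share_pct"]
        )
    else:
        fam = (
            gh.groupby(["compartment", "replicate", "family"])["mol_pct"]
            .sum()
            .rename("mol_pct")
            .reset_index()
        )
        totals = fam.groupby(["compartment", "replicate"])["mol_pct"].transform("sum")
        fam["gh_share_pct"] = 100.0 * fam["mol_pct"] / totals
        gh_shares = fam.drop(columns="mol_pct")

    per_rep = (
        out.groupby(["compartment", "replicate", "family"])["mol_pct"].sum().reset_index()
    )
    contrasts = (
        per_rep.groupby(["compartment", "family"])["mol_pct"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    return gh_shares, contrasts


def gh7_gh9_share(gh_shares: pd.DataFrame, compartment: str = "gut_fluid") -> pd.Series:
    """Combined GH7+GH9 share (%) among GHs, per replicate, in one compartment."""
    sub = gh_shares[
        (gh_shares["compartment"] == compartment)
        & (gh_shares["family"].isin(["GH7", "GH9"]))
    ]
    return sub.groupby("replicate")["gh_share_pct"].sum()
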