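"""Bundled reference estimates for four D2-receptor agonists.

Measured kinetic and potency estimates for dopamine (DA), p-tyramine, and
the two 5-OH-DPAT enantiomers at the wild-type (WT) and S193A mutant D2
receptor, as obtained with the GIRK-current assay this package models.
They serve three roles:

* ground-truth ``(k_on, k_off, efficacy)`` sets for the synthetic-data
  generator, so parameter-recovery tests run at realistic values;
* printed-constant inputs for the deterministic arithmetic checks
  (kinetic pK_d, SEM propagation, fold changes, rank correlation);
* the experimental design of the bundled simulated study (per-ligand
  washout concentrations and fit windows).

Units: rate constants s^-1 and M^-1 s^-1; concentrations molar;
pEC50/pK_d in -log10(M); efficacy (Top) dimensionless, DA-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import LigandKinetics

WT = "WT"
S193A = "S193A"

DA = "DA"
PTYR = "p-tyramine"
S_DPAT = "(S)-5-OH-DPAT"
R_DPAT = "(R)-5-OH-DPAT"

#: Canonical row order of the summary tables.
LIGAND_ORDER = (DA, PTYR, S_DPAT, R_DPAT)
RECEPTOR_ORDER = (WT, S193A)


@dataclass(frozen=True)
class ReferenceCondition:
    """One ligand x receptor condition with its published-style estimates."""

    ligand: str
    receptor: str
    pec50: float
    pec50_sem: float
    ec50_nm: float          # EC50 as printed, nM
    n_cr: str               # oocytes contributing concentration-response data
    k_off: float
    k_off_sem: float
    n_koff: int
    k_on: float
    k_on_sem: float
    n_kon: str
    pkd: float              # printed kinetic pK_d
    pkd_sem: float          # printed pK_d SEM
    top: float              # relative efficacy (fitted Top, DA-normalized)
    top_sem: float
    washout_concentration: float   # molar, 13-s application used for k_off
    washout_window_s: float        # monoexponential fit window after washout

    @property
    def kinetics(self) -> LigandKinetics:
        """Ground-truth kinetics for simulation (efficacy capped at 1)."""
        return LigandKinetics(
            name=f"{self.ligand}/{self.receptor}",
            k_on=self.k_on,
            k_off=self.k_off,
            efficacy=min(self.top, 1.0),
        )


REFERENCE_CONDITIONS: tuple[ReferenceCondition, ...] = (
    ReferenceCondition(DA, WT, 7.70, 0.07, 20, "5", 0.197, 0.012, 6,
                       9.70e7, 1.23e7, "3-8", 8.69, 0.14, 1.00, 0.02,
                       10e-9, 42.0),
    ReferenceCondition(PTYR, WT, 4.00, 0.21, 100_000, "6", 0.123, 0.008, 7,
                       4.94e3, 1.15e3, "5-7", 4.61, 0.24, 0.09, 0.01,
                       10e-6, 42.0),
    ReferenceCondition(S_DPAT, WT, 8.28, 0.08, 5, "11", 0.028, 0.010, 4,
                       2.86e7, 0.31e7, "5-9", 9.01, 0.35, 0.52, 0.01,
                       10e-9, 104.0),
    ReferenceCondition(R_DPAT, WT, 6.85, 0.16, 141, "11", 0.030, 0.008, 5,
                       8.65e5, 1.21e5, "3-8", 7.46, 0.30, 0.11, 0.01,
                       300e-9, 104.0),
    ReferenceCondition(DA, S193A, 5.03, 0.04, 9333, "8", 0.207, 0.012, 8,
                       3.69e4, 0.48e4, "4-7", 5.25, 0.14, 1.04, 0.04,
                       10e-6, 24.0),
    ReferenceCondition(PTYR, S193A, 4.32, 0.12, 47_863, "6-12", 0.112, 0.008, 5,
                       9.41e3, 2.34e3, "4-6", 4.93, 0.26, 0.37, 0.01,
                       1e-3, 24.0),
    ReferenceCondition(S_DPAT, S193A, 6.56, 0.05, 275, "12", 0.096, 0.009, 6,
                       2.82e6, 0.34e6, "5-8", 7.47, 0.15, 0.64, 0.01,
                       1e-6, 24.0),
    ReferenceCondition(R_DPAT, S193A, 7.07, 0.08, 85, "14", 0.069, 0.008, 6,
                       1.95e6, 0.15e6, "4-7", 7.45, 0.14, 0.63, 0.02,
                       300e-9, 24.0),
)


def get_condition(ligand: str, receptor: str) -> ReferenceCondition:
    """Look up one reference condition by ligand and receptor."""
    for cond in REFERENCE_CONDITIONS:
        if cond.ligand == ligand and cond.receptor == receptor:
            return cond
    raise KeyError(f"no reference condition for {ligand!r} at {receptor!r}")


#: Published cross-ligand rank correlation between pEC50 and kinetic pK_d.
SPEARMAN_RHO = 0.9048
SPEARMAN_P = 0.0046

#: Published WT -> S193A potency fold reductions and efficacy fold increases.
POTENCY_FOLD_DA = 467.0
POTENCY_FOLD_S_DPAT = 52.0
EFFICACY_FOLD_R_DPAT = 5.7
EFFICACY_FOLD_PTYR = 4.1

#: Expected relative-change arrow grid (ligand -> potency, efficacy, k_off, k_on).
ARROW_GRID = {
    DA: ("↓↓↓", "−", "−", "↓↓↓"),
    PTYR: ("↑", "↑", "−", "↑"),
    S_DPAT: ("↓↓", "−", "↑", "↓↓"),
    R_DPAT: ("↑", "↑↑", "↑", "↑"),
}

#: Maximally effective DA concentration used to normalize responses, molar.
REFERENCE_DA_CONCENTRATION = {WT: 1e-6, S193A: 300e-6}

#: Reported summary ANOVA F statistics (comparison of pEC50s across
#: agonist and genotype).  Raw per-oocyte data are unavailable and group
#: sizes are given as ranges, so these are carried for context only and
#: are never recomputed or asserted.
ANOVA_F_REPORTED = {"agonist": 281.8, "genotype": 139.2, "interaction": 79.98}
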