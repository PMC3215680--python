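"""Disease-level kernels controlling how information is shared across diseases.

Four choices of K_disease define the four prioritization variants:

=======  ======================  ==========================================
variant  disease kernel          sharing of disease-gene information
=======  ======================  ==========================================
1        Dirac (identity)        none: each disease treated independently
2        1 + Dirac               uniform sharing across all diseases
3        phenotype similarity    sharing weighted by phenotypic similarity
4        Dirac + phenotype       phenotypic sharing plus disease identity
=======  ======================  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data_model_io import DiseaseIndex, KernelMatrix

__all__ = [
    "PhenotypeSimilarity",
    "dirac_kernel",
    "multitask_kernel",
    "phenotype_kernel",
    "phenotype_plus_dirac",
    "disease_kernel_for_variant",
]

_ASYM_TOL = 1e-6
_CLIP_TRIGGER = 1e-6


@dataclass
class PhenotypeSimilarity:
    """Raw pairwise phenotype-similarity matrix over diseases.

    Typically a text-mining correlation measure; it is *close to* but not
    guaranteed to be positive semidefinite, hence validated and repaired by
    :func:`phenotype_kernel` before kernel use.
    """

    index: DiseaseIndex
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.index)
        if self.values.shape != (m, m):
            raise ValueError(
                f"similarity shape {self.values.shape} does not match {m} diseases"
            )


def dirac_kernel(diseases: DiseaseIndex) -> KernelMatrix:
    """Identity kernel: K(D, D') = 1 if D = D', 0 otherwise. No sharing."""
    return KernelMatrix(
        index=diseases, values=np.eye(len(diseases)), source_name="dirac"
    )


def multitask_kernel(diseases: DiseaseIndex) -> KernelMatrix:
    """Uniform-sharing kernel K(D, D') = 1 + Dirac(D, D').

    The constant lets every known disease gene act as a (weaker) positive
    example for every other disease; the Dirac part keeps a disease's own
    genes twice as influential.
    """
    m = len(diseases)
    return KernelMatrix(
        index=diseases, values=np.ones((m, m)) + np.eye(m), source_name="multitask"
    )


def phenotype_kernel(sim: PhenotypeSimilarity) -> KernelMatrix:
    """Validated phenotype kernel from a raw similarity matrix.

    Steps: symmetrize (S + S')/2 (erroring if the asymmetry exceeds 1e-6);
    clip negative eigenvalues to zero when the smallest eigenvalue falls
    below -1e-6 (minimal-perturbation projection onto the PSD cone); rescale
    to unit diagonal so the Dirac addition in the variant-4 kernel has a
    fixed relative weight of 1.
    """
    S = sim.values
    asym = float(np.max(np.abs(S - S.T)))
    if asym > _ASYM_TOL:
        raise ValueError(f"phenotype similarity asymmetric beyond tolerance: {asym:.3g}")
    S = (S + S.T) / 2.0
    d = np.diag(S)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive self-similarity for {[sim.index.ids[i] for i in bad[:5]]}"
        )
    w, V = scipy.linalg.eigh(S)
    if w[0] < -_CLIP_TRIGGER:
        S = (V * np.clip(w, 0.0, None)) @ V.T
        S = (S + S.T) / 2.0
        d = np.diag(S)
        if np.any(d <= 0):
            raise ValueError("phenotype similarity degenerate after PSD repair")
    s = 1.0 / np.sqrt(d)
    values = S * np.outer(s, s)
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(index=sim.index, values=values, source_name="phenotype")


def phenotype_plus_dirac(sim: PhenotypeSimilarity) -> KernelMatrix:
    """Phenotype kernel plus the Dirac kernel (diagonal 2).

    Distinguishes diseases with near-identical phenotype descriptions by
    giving extra weight to the genes of the disease of interest itself.
    """
    K = phenotype_kernel(sim)
    return KernelMatrix(
        index=K.index,
        values=K.values + np.eye(len(K.index)),
        source_name="phenotype+dirac",
    )


def disease_kernel_for_variant(
    variant: int,
    diseases: DiseaseIndex,
    phenotype: PhenotypeSimilarity | None = None,
) -> KernelMatrix:
    """The disease kernel prescribed for a given prioritization variant."""
    if variant == 1:
        return dirac_kernel(diseases)
    if variant == 2:
        return multitask_kernel(diseases)
    if variant in (3, 4):
        if phenotype is None:
            raise ValueError(f"variant {variant} requires a phenotype similarity matrix")
        if phenotype.index != diseases:
            raise ValueError("phenotype similarity index does not match disease index")
        return phenotype_kernel(phenotype) if variant == 3 else phenotype_plus_dirac(phenotype)
    raise ValueError(f"unknown variant {variant}")
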