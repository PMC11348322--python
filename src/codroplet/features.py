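"""Per-protein feature bundles: AlphaFold2-style representations.

The model consumes, for every protein, three fixed-dimension arrays that in
production come from the Evoformer / structure module of AlphaFold2:

* ``f_msa``   — single (MSA-derived) representation, shape ``(L, 384)``
* ``f_pair``  — pair representation, shape ``(L, L, 128)``
* ``f_struc`` — structure-module representation, shape ``(L, 384)``

Running AlphaFold2 is out of scope here, so this module provides two routes:
an HDF5-backed store for externally computed bundles, and a deterministic
surrogate generator.  The surrogate plants a low-dimensional latent
"compatibility" vector per protein into all three representations through
fixed seed-derived projection bases, so that (a) the latent vector is exactly
linearly decodable from the ``f_msa`` row means at zero noise and (b) pairs
of proteins that share a latent cluster are distinguishable from pairs that
do not — the property the training tests exploit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "C_MSA",
    "C_PAIR",
    "C_STRUC",
    "FeatureBundle",
    "LatentProfile",
    "generate_surrogate_features",
    "make_latent_profiles",
    "generate_cohort",
    "save_features",
    "load_features",
    "list_features",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

C_MSA = 384
C_PAIR = 128
C_STRUC = 384

#: width of the per-residue embedding the surrogate pair features are built from
_PAIR_EMBED_DIM = 16


@dataclass
class FeatureBundle:
    """The three per-protein representations, sharing residue count ``L``."""

    protein_id: str
    f_msa: np.ndarray
    f_pair: np.ndarray
    f_struc: np.ndarray

    def __post_init__(self) -> None:
        self.f_msa = np.asarray(self.f_msa, dtype=np.float64)
        self.f_pair = np.asarray(self.f_pair, dtype=np.float64)
        self.f_struc = np.asarray(self.f_struc, dtype=np.float64)
        L = self.f_msa.shape[0]
        if self.f_msa.shape != (L, C_MSA):
            raise ValueError(f"f_msa must have shape (L, {C_MSA}), got {self.f_msa.shape}")
        if self.f_pair.shape != (L, L, C_PAIR):
            raise ValueError(f"f_pair must have shape (L, L, {C_PAIR}), got {self.f_pair.shape}")
        if self.f_struc.shape != (L, C_STRUC):
            raise ValueError(f"f_struc must have shape (L, {C_STRUC}), got {self.f_struc.shape}")
        if L < 1:
            raise ValueError("residue count must be >= 1")
        for name in ("f_msa", "f_pair", "f_struc"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def length(self) -> int:
        return self.f_msa.shape[0]


@dataclass
class LatentProfile:
    """Latent compatibility state planted into a surrogate bundle.

    ``compatibility_vector`` drives pairwise co-condensation in the synthetic
    world: proteins whose vectors coincide (same ``cluster_id``) form the
    positive class of the planted-label datasets.
    """

    protein_id: str
    compatibility_vector: np.ndarray
    cluster_id: int = 0

    def __post_init__(self) -> None:
        self.compatibility_vector = np.asarray(self.compatibility_vector, dtype=np.float64)
        if self.compatibility_vector.ndim != 1 or self.compatibility_vector.size < 1:
            raise ValueError("compatibility_vector must be a nonempty 1-D vector")
        if not np.all(np.isfinite(self.compatibility_vector)):
            raise ValueError("compatibility_vector contains non-finite values")


def _encode_sequence(sequence: str) -> np.ndarray:
    """One-hot encode ``sequence``; reject anything outside the 20-letter code."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    onehot = np.zeros((len(sequence), 20))
    for pos, aa in enumerate(sequence):
        idx = _AA_INDEX.get(aa.upper())
        if idx is None:
            raise ValueError(
                f"invalid residue {aa!r} at position {pos + 1}: "
                f"sequences must use the 20-letter alphabet {AMINO_ACIDS}"
            )
        onehot[pos, idx] = 1.0
    return onehot


@dataclass
class _Bases:
    """Fixed projection bases shared by every bundle generated from one seed."""

    msa_aa: np.ndarray
    msa_lat: np.ndarray
    struc_aa: np.ndarray
    struc_lat: np.ndarray
    embed_aa: np.ndarray
    embed_lat: np.ndarray
    pair_proj: np.ndarray
    d_lat: int = field(default=8)


_BASES_CACHE: dict[tuple[int, int], _Bases] = {}


def _bases(seed: int, d_lat: int) -> _Bases:
    key = (int(seed), int(d_lat))
    if key not in _BASES_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0BA5E5]))
        _BASES_CACHE[key] = _Bases(
            msa_aa=rng.standard_normal((20, C_MSA)),
            msa_lat=rng.standard_normal((d_lat, C_MSA)),
            struc_aa=rng.standard_normal((20, C_STRUC)),
            struc_lat=rng.standard_normal((d_lat, C_STRUC)),
            embed_aa=rng.standard_normal((20, _PAIR_EMBED_DIM)) / np.sqrt(_PAIR_EMBED_DIM),
            embed_lat=rng.standard_normal((d_lat, _PAIR_EMBED_DIM)) / np.sqrt(_PAIR_EMBED_DIM),
            pair_proj=rng.standard_normal((_PAIR_EMBED_DIM, C_PAIR)),
            d_lat=d_lat,
        )
    return _BASES_CACHE[key]


def _noise_rng(seed: int, protein_id: str, sequence: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{protein_id}|{sequence}".encode()).digest()
    entropy = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), entropy]))


def generate_surrogate_features(
    sequence: str,
    profile: LatentProfile,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> FeatureBundle:
    """Build a surrogate feature bundle for one protein.

    The bundle is a deterministic function of ``(sequence, profile, seed)``;
    ``noise_sd`` adds Gaussian noise from a stream keyed by the protein, so
    regenerating the same protein reproduces it bit for bit.  Residue
    identity and the profile's compatibility vector are embedded through
    projection bases drawn once from ``seed`` and shared across proteins;
    ``f_pair[i, j]`` is a projection of the elementwise product of the two
    residues' embeddings, giving the attention bias a genuine pairwise
    signal to exploit.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    onehot = _encode_sequence(sequence)
    v = profile.compatibility_vector
    b = _bases(seed, v.size)

    f_msa = onehot @ b.msa_aa + v @ b.msa_lat
    f_struc = onehot @ b.struc_aa + v @ b.struc_lat
    u = onehot @ b.embed_aa + v @ b.embed_lat  # (L, k) per-residue embedding
    f_pair = (u[:, None, :] * u[None, :, :]) @ b.pair_proj

    if noise_sd > 0:
        rng = _noise_rng(seed, profile.protein_id, sequence)
        f_msa = f_msa + noise_sd * rng.standard_normal(f_msa.shape)
        f_pair = f_pair + noise_sd * rng.standard_normal(f_pair.shape)
        f_struc = f_struc + noise_sd * rng.standard_normal(f_struc.shape)

    return FeatureBundle(profile.protein_id, f_msa, f_pair, f_struc)


def make_latent_profiles(
    protein_ids: list[str],
    n_clusters: int = 2,
    d_lat: int = 8,
    seed: int = 0,
) -> list[LatentProfile]:
    """Assign proteins to latent clusters with unit-norm center vectors.

    Cluster centers are drawn once from ``seed``; proteins are assigned
    round-robin so cluster sizes differ by at most one.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC1A57E]))
    centers = rng.standard_normal((n_clusters, d_lat))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    return [
        LatentProfile(pid, centers[i % n_clusters], cluster_id=i % n_clusters)
        for i, pid in enumerate(protein_ids)
    ]


def generate_cohort(
    n_proteins: int,
    length: int | tuple[int, int] = (8, 12),
    n_clusters: int = 2,
    d_lat: int = 8,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Generate a synthetic protein cohort: sequences, profiles and bundles.

    Returns ``(sequences, profiles, bundles)`` where ``sequences`` maps
    protein id to a random amino-acid string.  Sequence composition is
    independent of the cluster, so labels are only recoverable from the
    planted latent signal, not from sequence statistics.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0407]))
    ids = [f"P{i:04d}" for i in range(n_proteins)]
    lo, hi = (length, length) if isinstance(length, int) else length
    sequences = {
        pid: "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(lo, hi + 1)))
        for pid in ids
    }
    profiles = make_latent_profiles(ids, n_clusters=n_clusters, d_lat=d_lat, seed=seed)
    bundles = [
        generate_surrogate_features(sequences[p.protein_id], p, noise_sd=noise_sd, seed=seed)
        for p in profiles
    ]
    return sequences, profiles, bundles


# ---------------------------------------------------------------------------
# HDF5 feature store: /<protein_id>/{f_msa,f_pair,f_struc}
# ---------------------------------------------------------------------------

def save_features(store_path, bundles) -> None:
    """Write bundles into an HDF5 store, one group per protein id."""
    with h5py.File(store_path, "a") as fh:
        for bundle in bundles:
            if bundle.protein_id in fh:
                del fh[bundle.protein_id]
            grp = fh.create_group(bundle.protein_id)
            grp.create_dataset("f_msa", data=bundle.f_msa)
            grp.create_dataset("f_pair", data=bundle.f_pair)
            grp.create_dataset("f_struc", data=bundle.f_struc)


def load_features(store_path, protein_id: str) -> FeatureBundle:
    """Load one protein's bundle; unknown ids raise with the available ids."""
    with h5py.File(store_path, "r") as fh:
        if protein_id not in fh:
            available = ", ".join(sorted(fh.keys()))
            raise KeyError(
                f"protein {protein_id!r} not in feature store; available: {available}"
            )
        grp = fh[protein_id]
        return FeatureBundle(
            protein_id,
            grp["f_msa"][()],
            grp["f_pair"][()],
            grp["f_struc"][()],
        )


def list_features(store_path) -> list[str]:
    """Protein ids present in a feature store."""
    with h5py.File(store_path, "r") as fh:
        return sorted(fh.keys())
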