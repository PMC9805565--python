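"""SMURF training loops.

Phase 1, BasicAlign, fits only the convolutional encoder by pulling every
sequence's soft profile toward the column-average profile (columns become
residue-pure when sequences agree on an alignment).  Phase 2, TrainMRF,
jointly descends the masked-language-model loss in the encoder and MRF
parameters, letting the model revise the alignment while it learns pairwise
couplings.  MLM-GREMLIN is the fixed-alignment baseline: the same MLM loss
and optimizer on hard one-hot profiles from a given MSA, MRF parameters
only.

All loops are plain Adam with a fixed learning rate, full-batch by default,
and draw masks (and minibatches, if any) from a deterministic per-step seed
stream so two runs with equal seeds are bit-identical, and TrainMRF with a
frozen encoder on fixed profiles reproduces MLM-GREMLIN step for step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _autodiff as ad
from .lam import (EncoderParams, PROTEIN_ALPHABET, SoftMSA, init_encoder,
                  lam_chain_t, one_hot)
from .mrf import MRFParams, mlm_loss_t, sample_mask, symmetrize_couplings, _sym_t
from .smooth_align import AlignParams

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 0.05
    steps: int = 100
    batch_size: Optional[int] = None  # None = full batch
    temperature: float = 1.0
    seed: int = 0
    mask_rate: float = 0.15
    lam_v: float = 0.01
    lam_w: float = 0.01

    def __post_init__(self):
        if self.learning_rate <= 0 or self.steps < 1 or self.temperature <= 0:
            raise ValueError("learning_rate, steps and temperature must be positive")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class SmurfModel:
    encoder: EncoderParams
    align_params: AlignParams
    mrf: MRFParams


DEFAULT_ALIGN = AlignParams(temperature=1.0, open=-6.0, extend=-2.0,
                            gap_mode="affine", align_mode="local",
                            restrict_turns=True)


class Adam:
    """Plain Adam with fixed step size over a dict of numpy parameters."""

    def __init__(self, params: dict, lr: float, b1: float = 0.9,
                 b2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _step_seeds(seed: int, steps: int) -> np.ndarray:
    """Deterministic (steps, 2) seed table: column 0 masks, column 1 batches."""
    return np.random.SeedSequence(seed).generate_state(2 * steps).reshape(steps, 2)


def _batch_indices(B: int, batch_size: Optional[int], seed: int) -> np.ndarray:
    if batch_size is None or batch_size >= B:
        return np.arange(B)
    rng = np.random.default_rng(int(seed))
    return np.sort(rng.choice(B, size=batch_size, replace=False))


def _check_finite(loss: float, step: int, phase: str) -> None:
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"{phase} loss became non-finite at step {step}; "
            "try a lower learning rate")


# ---------------------------------------------------------------------------
# BasicAlign
# ---------------------------------------------------------------------------

def basic_align_loss_t(profiles_t, gap_t=None, gap_weight: float = 0.0):
    """Sum of squared differences between each soft profile row and the
    column-average profile, plus an optional linear gap-mass penalty.

    The squared-difference term alone has a degenerate minimum where the
    encoder drives all alignment mass into gaps (every profile row equals
    the all-zero mean); the gap penalty removes that direction while leaving
    the column-purity signal intact.
    """
    B = profiles_t.shape[0]
    mean = ad.tsum(profiles_t, axis=0, keepdims=True) * (1.0 / B)
    diff = profiles_t - mean
    loss = ad.tsum(diff * diff)
    if gap_t is not None and gap_weight != 0.0:
        loss = loss + gap_weight * ad.tsum(gap_t)
    return loss


def basic_align_loss(seqs: Sequence[str], query: str, enc: EncoderParams,
                     params: AlignParams,
                     alphabet: str = PROTEIN_ALPHABET) -> float:
    """Numpy-facing BasicAlign objective for a set of raw sequences."""
    if len(seqs) < 2:
        raise ValueError("BasicAlign needs at least two sequences")
    onehots = [one_hot(s, alphabet) for s in seqs]
    q = one_hot(query, alphabet)
    kernel_t = ad.const(enc.kernel.reshape(-1, enc.filters))
    bias_t = ad.const(enc.bias)
    profiles, _, _, _ = lam_chain_t(onehots, q, kernel_t, bias_t, params)
    return float(basic_align_loss_t(profiles).data)


def run_basic_align(seqs: Sequence[str], query: str, cfg: TrainConfig,
                    enc_init: Optional[EncoderParams] = None,
                    align_params: Optional[AlignParams] = None,
                    window_half_width: int = 9, filters: int = 512,
                    alphabet: str = PROTEIN_ALPHABET,
                    gap_weight: float = 1.0,
                    history: Optional[list] = None) -> EncoderParams:
    """Gradient descent on the BasicAlign loss; returns the final encoder."""
    if len(seqs) < 2:
        raise ValueError("BasicAlign needs at least two sequences")
    A = len(alphabet)
    if enc_init is None:
        enc_init = init_encoder(window_half_width, A, filters, cfg.seed)
    if align_params is None:
        align_params = _align_from_cfg(cfg)
    onehots = [one_hot(s, alphabet) for s in seqs]
    q = one_hot(query, alphabet)
    F = enc_init.filters
    params = {"kernel": enc_init.kernel.reshape(-1, F).copy(),
              "bias": enc_init.bias.copy()}
    opt = Adam(params, cfg.learning_rate)
    seeds = _step_seeds(cfg.seed, cfg.steps)
    B = len(onehots)
    for step in range(cfg.steps):
        idx = _batch_indices(B, cfg.batch_size, seeds[step, 1])
        kernel_t, bias_t = ad.var(params["kernel"]), ad.var(params["bias"])
        profiles, gap_t, _, _ = lam_chain_t([onehots[i] for i in idx], q,
                                            kernel_t, bias_t, align_params)
        loss = basic_align_loss_t(profiles, gap_t, gap_weight)
        _check_finite(float(loss.data), step, "BasicAlign")
        gk, gb = ad.grad(loss, [kernel_t, bias_t])
        opt.step({"kernel": gk, "bias": gb})
        if history is not None:
            history.append((step, float(loss.data)))
        logger.debug("BasicAlign step %d loss %.6f", step, float(loss.data))
    return EncoderParams(params["kernel"].reshape(enc_init.kernel.shape),
                         params["bias"])


def _align_from_cfg(cfg: TrainConfig) -> AlignParams:
    return AlignParams(temperature=cfg.temperature, open=DEFAULT_ALIGN.open,
                       extend=DEFAULT_ALIGN.extend, gap_mode="affine",
                       align_mode="local", restrict_turns=True)


# ---------------------------------------------------------------------------
# TrainMRF (joint) and MLM-GREMLIN (fixed alignment)
# ---------------------------------------------------------------------------

def run_train_mrf(seqs: Sequence[str], query: str, enc_init: EncoderParams,
                  cfg: TrainConfig, align_params: Optional[AlignParams] = None,
                  alphabet: str = PROTEIN_ALPHABET,
                  freeze_encoder: bool = False,
                  fixed_profiles: Optional[SoftMSA] = None,
                  mrf_init: Optional[MRFParams] = None,
                  history: Optional[list] = None,
                  callback=None, callback_every: int = 0) -> SmurfModel:
    """Jointly descend the MLM loss in encoder and MRF parameters.

    With ``freeze_encoder`` and ``fixed_profiles`` the loop degenerates to
    MRF-only training on the given profiles (the MLM-GREMLIN setting).
    """
    if align_params is None:
        align_params = _align_from_cfg(cfg)
    A = len(alphabet)
    L = len(query)
    onehots = [one_hot(s, alphabet) for s in seqs]
    q = one_hot(query, alphabet)
    F = enc_init.filters
    params = {"kernel": enc_init.kernel.reshape(-1, F).copy(),
              "bias": enc_init.bias.copy(),
              "fields": (np.zeros((L, A)) if mrf_init is None
                         else mrf_init.fields.copy()),
              "couplings": (np.zeros((L, L, A, A)) if mrf_init is None
                            else mrf_init.couplings.copy())}
    trainable = ["fields", "couplings"] if freeze_encoder else \
        ["kernel", "bias", "fields", "couplings"]
    opt = Adam({k: params[k] for k in trainable}, cfg.learning_rate)
    seeds = _step_seeds(cfg.seed, cfg.steps)
    B = len(onehots)
    if freeze_encoder and fixed_profiles is None:
        # encoder is constant: evaluate the LAM chain once up front
        prof0, gap0, _, _ = lam_chain_t(onehots, q, ad.const(params["kernel"]),
                                        ad.const(params["bias"]), align_params)
        fixed_profiles = SoftMSA(prof0.data, gap0.data)
    for step in range(cfg.steps):
        idx = _batch_indices(B, cfg.batch_size, seeds[step, 1])
        v_t = ad.var(params["fields"])
        w_t = ad.var(params["couplings"])
        Wsym = _sym_t(w_t, L)
        wrt = [v_t, w_t]
        if fixed_profiles is not None:
            prof_t = ad.const(fixed_profiles.profiles[idx])
            gap_t = ad.const(fixed_profiles.gap_mass[idx])
        else:
            kernel_t = (ad.const if freeze_encoder else ad.var)(params["kernel"])
            bias_t = (ad.const if freeze_encoder else ad.var)(params["bias"])
            prof_t, gap_t, _, _ = lam_chain_t([onehots[i] for i in idx], q,
                                              kernel_t, bias_t, align_params)
            if not freeze_encoder:
                wrt = [kernel_t, bias_t, v_t, w_t]
        mask = sample_mask(len(idx), L, cfg.mask_rate, int(seeds[step, 0]))
        loss = mlm_loss_t(prof_t, gap_t, mask.masked, v_t, Wsym,
                          cfg.lam_v, cfg.lam_w, len(idx))
        _check_finite(float(loss.data), step, "TrainMRF")
        grads = dict(zip(["fields", "couplings"] if len(wrt) == 2 else
                         ["kernel", "bias", "fields", "couplings"],
                         ad.grad(loss, wrt)))
        opt.step(grads)
        if history is not None:
            history.append((step, float(loss.data)))
        if callback is not None and callback_every and (step + 1) % callback_every == 0:
            callback(step + 1, params)
        logger.debug("TrainMRF step %d loss %.6f", step, float(loss.data))
    enc = EncoderParams(params["kernel"].reshape(enc_init.kernel.shape),
                        params["bias"])
    mrf = MRFParams(params["fields"], symmetrize_couplings(params["couplings"]))
    return SmurfModel(enc, align_params, mrf)


def msa_to_profiles(msa_rows: Sequence[str], alphabet: str = PROTEIN_ALPHABET) -> SoftMSA:
    """Hard one-hot profiles in query coordinates from an MSA.

    Lowercase (insertion) columns are dropped per the A3M convention; '-'
    and unknown residues leave all-zero rows (pure gap mass).
    """
    rows = ["".join(c for c in r if not c.islower()) for r in msa_rows]
    L = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != L:
            raise ValueError(f"MSA row {k} has aligned length {len(r)}, expected {L}")
    idx = {c: a for a, c in enumerate(alphabet)}
    B, A = len(rows), len(alphabet)
    prof = np.zeros((B, L, A))
    for s, r in enumerate(rows):
        for i, c in enumerate(r):
            a = idx.get(c.upper())
            if a is not None:
                prof[s, i, a] = 1.0
    return SoftMSA(prof, 1.0 - prof.sum(axis=2))


def run_mlm_gremlin(msa_rows: Sequence[str], cfg: TrainConfig,
                    alphabet: str = PROTEIN_ALPHABET,
                    history: Optional[list] = None) -> MRFParams:
    """Train the MRF alone on a fixed alignment with the MLM objective."""
    profiles = msa_to_profiles(msa_rows, alphabet)
    B, L, A = profiles.profiles.shape
    params = {"fields": np.zeros((L, A)), "couplings": np.zeros((L, L, A, A))}
    opt = Adam(params, cfg.learning_rate)
    seeds = _step_seeds(cfg.seed, cfg.steps)
    for step in range(cfg.steps):
        idx = _batch_indices(B, cfg.batch_size, seeds[step, 1])
        v_t = ad.var(params["fields"])
        w_t = ad.var(params["couplings"])
        Wsym = _sym_t(w_t, L)
        mask = sample_mask(len(idx), L, cfg.mask_rate, int(seeds[step, 0]))
        loss = mlm_loss_t(ad.const(profiles.profiles[idx]),
                          ad.const(profiles.gap_mass[idx]),
                          mask.masked, v_t, Wsym, cfg.lam_v, cfg.lam_w, len(idx))
        _check_finite(float(loss.data), step, "MLM-GREMLIN")
        gv, gw = ad.grad(loss, [v_t, w_t])
        opt.step({"fields": gv, "couplings": gw})
        if history is not None:
            history.append((step, float(loss.data)))
        logger.debug("MLM-GREMLIN step %d loss %.6f", step, float(loss.data))
    return MRFParams(params["fields"], symmetrize_couplings(params["couplings"]))


def refit_mrf_ensemble(seqs: Sequence[str], query: str, encoder: EncoderParams,
                       cfg: TrainConfig, n: int,
                       align_params: Optional[AlignParams] = None,
                       alphabet: str = PROTEIN_ALPHABET):
    """Refit the MRF ``n`` times on the frozen learned alignment, varying the
    mask stream; returns the list of MRFParams.

    A single MLM refit is a noisy estimator of the coupling structure (the
    masks are random and the optimizer endpoint depends on them); averaging
    the contact scores of a few refits reduces the ranking variance
    substantially at negligible cost.
    """
    out = []
    for k in range(n):
        c = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + k})
        out.append(run_train_mrf(seqs, query, encoder, c,
                                 align_params=align_params, alphabet=alphabet,
                                 freeze_encoder=True).mrf)
    return out


def averaged_contact_scores(mrfs):
    """Mean of the APC-corrected contact-score matrices of several MRFs."""
    from .mrf import ContactScores, contact_scores

    acc = None
    for m in mrfs:
        s = contact_scores(m).scores
        acc = s if acc is None else acc + s
    return ContactScores(acc / len(mrfs))


def run_smurf(seqs: Sequence[str], query: str, basic_cfg: TrainConfig,
              mrf_cfg: TrainConfig, window_half_width: int = 9,
              filters: int = 64, alphabet: str = PROTEIN_ALPHABET,
              align_params: Optional[AlignParams] = None,
              gap_weight: float = 2.0, cycles: int = 1,
              refit_cfg: Optional[TrainConfig] = None,
              history: Optional[dict] = None) -> SmurfModel:
    """Full SMURF pipeline.

    BasicAlign learns the encoder; TrainMRF then adjusts encoder and MRF
    jointly on the MLM loss (minibatched -- the stochasticity is what lets
    the alignment escape register-jitter minima); finally the MRF is refit
    from zero with the encoder frozen, so the reported couplings come from a
    settled alignment.  ``cycles`` > 1 alternates joint adjustment and refit,
    feeding each refit MRF back in as the next joint phase's initialization.
    """
    if refit_cfg is None:
        refit_cfg = TrainConfig(steps=150, learning_rate=0.1,
                                seed=mrf_cfg.seed + 1000,
                                mask_rate=0.15, temperature=mrf_cfg.temperature,
                                lam_v=mrf_cfg.lam_v, lam_w=mrf_cfg.lam_w)
    h1 = [] if history is not None else None
    enc = run_basic_align(seqs, query, basic_cfg,
                          window_half_width=window_half_width,
                          filters=filters, alphabet=alphabet,
                          align_params=align_params, gap_weight=gap_weight,
                          history=h1)
    if history is not None:
        history["basic_align"] = h1
        history["train_mrf"] = []
        history["refit"] = []
    mrf_state = None
    model = None
    for cycle in range(cycles):
        h2 = [] if history is not None else None
        joint_cfg = TrainConfig(**{**mrf_cfg.__dict__, "seed": mrf_cfg.seed + cycle})
        model = run_train_mrf(seqs, query, enc, joint_cfg,
                              alphabet=alphabet, align_params=align_params,
                              mrf_init=mrf_state, history=h2)
        enc = model.encoder
        h3 = [] if history is not None else None
        rf_cfg = TrainConfig(**{**refit_cfg.__dict__, "seed": refit_cfg.seed + cycle})
        refit = run_train_mrf(seqs, query, enc, rf_cfg, alphabet=alphabet,
                              align_params=align_params, freeze_encoder=True,
                              history=h3)
        mrf_state = refit.mrf
        if history is not None:
            history["train_mrf"].append(h2)
            history["refit"].append(h3)
        model = SmurfModel(enc, model.align_params, refit.mrf)
    return model
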