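"""Structured variational deconvolution model.

Generative process per spot i with K cell states:

* state embeddings  u_k ~ N(0, 10 I) in D_z dimensions, heterogeneity σ_k;
* proportions       c_i ~ Dirichlet(α A_i) with the empirical prior A;
* latent            z_i | c_i, u ~ N(Σ_k c_ik u_k, Σ_k c_ik σ_k);
* library           l_i ~ logNormal(log l̃_i, 1) with the smoothed prior l̃;
* counts            x_ig ~ NegativeBinomial(mean l_i f(z_i)_g, dispersion θ_g),
  where f is a linear layer + softmax over genes.

The variational family mirrors the structure: q(u_k)=N(m_k, v_k),
q(l|x)=N(λ(x)) on the log scale, q(c|x)=Dirichlet(α γ(x)) and the mixture
posterior q(z|c,x)=N(Σ_k c_ik ζ_μ(k,x), Σ_k c_ik ζ_σ(k,x)). The encoders
λ, γ, ζ are one-hidden-layer ReLU networks on per-gene standardized log1p
counts (a single linear softmax cannot represent the empirical prior,
which is itself a nonlinear transform of the counts); the decoder f and
the image encoder ξ stay single-layer. With histology, ξ gives a second
Gaussian view on z and the views are fused by a product of experts
(precision weighting); training then optimizes the joint ELBO plus ``a``
times the view-specific marginal ELBOs.

Training uses Adam (lr 1e-3, exponential decay 0.98/epoch, 200 epochs,
minibatches of 32) with independent restarts, keeping the restart with the
best expression reconstruction. Two measures keep the symmetric likelihood
from locking the proportion encoder into an arbitrary head-to-state
assignment: the likelihood weight ramps linearly over the first third of
the epochs (the Dirichlet prior fixes the labeling first), and training
starts from an identifiable mixture configuration — the decoder f is
seeded with the anchor-spot expression profiles, the state embeddings m_k
with scaled latent corners, and the ζ heads at those embeddings — so the
reconstruction gradient with respect to the proportions points along
state-profile directions from the first step. Hidden layers use Kaiming
initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special as sps

from ._autodiff import (Adam, Tensor, digamma, gamma_rsample, kaiming_normal,
                        lgamma, log_softmax, normal_rsample, relu, softmax,
                        softplus)
from .core_io import PatchSet, SpotDataset
from .priors import PriorBundle

__all__ = [
    "GenerativeConfig",
    "VariationalState",
    "DeconvolutionResult",
    "nb_log_pmf",
    "poe_combine",
    "decode_mean_expression",
    "expression_elbo",
    "joint_elbo",
    "train",
    "infer",
    "predict_state_expression",
]

_VAR_FLOOR = 1e-4


@dataclass
class GenerativeConfig:
    """Hyperparameters of the generative model and its training loop."""

    K: int = 0                    # filled from the prior bundle when 0
    D_z: int = 10
    alpha: float = 50.0
    u_prior_var: float = 10.0
    lib_prior_sd: float = 1.0
    poe_enabled: bool = False
    ib_weight: float = 5.0        # weight `a` on the view-specific ELBOs
    epochs: int = 200
    lr: float = 1e-3
    lr_decay: float = 0.98
    restarts: int = 3
    seed: int = 0
    batch_size: int = 32
    hidden: int = 256             # encoder hidden width
    warmup_frac: float = 1 / 3    # likelihood warm-up, fraction of epochs
    theta_init: float = 10.0

    def __post_init__(self):
        if self.alpha <= 0 or self.D_z < 1 or self.ib_weight < 0:
            raise ValueError("invalid configuration")


@dataclass
class VariationalState:
    """Learned variational parameters and networks, plus training traces."""

    params: dict[str, Tensor]
    cfg: GenerativeConfig
    priors: PriorBundle
    elbo_trace: list[float] = field(default_factory=list)
    restart_traces: list[list[float]] = field(default_factory=list)
    restart_recon: list[float] = field(default_factory=list)
    feat_stats: tuple[np.ndarray, np.ndarray] | None = None
    trained: bool = False

    def parameter_list(self) -> list[Tensor]:
        return list(self.params.values())


@dataclass
class DeconvolutionResult:
    """Posterior summaries: proportions, latents, libraries, reconstructions."""

    c: np.ndarray                  # (S, K) rows on the simplex
    z: np.ndarray                  # (S, D_z)
    l: np.ndarray                  # (S,) positive
    recon_expr: np.ndarray         # (S, G)
    state_expr: np.ndarray         # (K, G) rows sum to 1
    spot_ids: list[str]
    state_names: list[str]
    recon_img: np.ndarray | None = None


# ---------------------------------------------------------------------------
# distribution primitives


def nb_log_pmf(x, mean, theta):
    """Negative-binomial log pmf with mean ``mean`` and inverse-dispersion
    ``theta`` (variance mean + mean^2/theta). Numpy arrays/scalars."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(x < 0) or np.any(mean <= 0) or np.any(theta <= 0):
        raise ValueError("require x >= 0, mean > 0, theta > 0")
    return (sps.gammaln(x + theta) - sps.gammaln(theta) - sps.gammaln(x + 1.0)
            + theta * (np.log(theta) - np.log(theta + mean))
            + x * (np.log(mean) - np.log(theta + mean)))


def _nb_log_pmf_t(x: Tensor, mean: Tensor, theta: Tensor) -> Tensor:
    return (lgamma(x + theta) - lgamma(theta) - lgamma(x + 1.0)
            + theta * (theta.log() - (theta + mean).log())
            + x * (mean.log() - (theta + mean).log()))


def poe_combine(mu1, var1, mu2, var2):
    """Product-of-experts fusion of two Gaussians (inputs are variances).

    Returns the precision-weighted mean and the combined variance
    ``1 / (1/var1 + 1/var2)``. Works on numpy arrays and autodiff tensors.
    """
    for v in (var1, var2):
        arr = v.data if isinstance(v, Tensor) else np.asarray(v)
        if np.any(arr <= 0):
            raise ValueError("variances must be positive")
    prec = 1.0 / var1 + 1.0 / var2
    mu = (mu1 / var1 + mu2 / var2) / prec
    return mu, 1.0 / prec


def _kl_normal(qm, qv, pm, pv):
    """KL(N(qm, qv) || N(pm, pv)), elementwise (variances)."""
    if any(isinstance(t, Tensor) for t in (qm, qv, pm, pv)):
        qv_l = qv.log() if isinstance(qv, Tensor) else Tensor(np.log(qv))
        pv_l = pv.log() if isinstance(pv, Tensor) else Tensor(np.log(pv))
        return 0.5 * ((pv_l - qv_l) + (qv + (qm - pm) ** 2) / pv - 1.0)
    return 0.5 * (np.log(pv) - np.log(qv) + (qv + (qm - pm) ** 2) / pv - 1.0)


def _kl_dirichlet(a: Tensor, b: np.ndarray) -> Tensor:
    """KL(Dir(a) || Dir(b)) per row; `a` is a Tensor, `b` a constant."""
    b = Tensor(b)
    a0 = a.sum(axis=1, keepdims=True)
    b0 = b.sum(axis=1, keepdims=True)
    t = ((a - b) * (digamma(a) - digamma(a0))).sum(axis=1, keepdims=True)
    kl = (lgamma(a0) - lgamma(b0)
          - (lgamma(a) - lgamma(b)).sum(axis=1, keepdims=True) + t)
    return kl.reshape(-1)


def decode_mean_expression(z: np.ndarray, f: tuple[np.ndarray, np.ndarray]
                           ) -> np.ndarray:
    """Decoder f: softmax(z W + b) — normalized mean expression per gene."""
    W, b = f
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite latent input")
    logits = z @ W + b
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    out = e / e.sum(axis=1, keepdims=True)
    return out[0] if out.shape[0] == 1 else out


# ---------------------------------------------------------------------------
# parameters


def _init_params(G: int, K: int, cfg: GenerativeConfig,
                 rng: np.random.Generator,
                 patch_dim: int | None = None,
                 anchor_logprof: np.ndarray | None = None
                 ) -> dict[str, Tensor]:
    """Initialize all parameters.

    Hidden layers use Kaiming-normal weights. When `anchor_logprof` (the
    (K, G) log mean expression over each state's anchor spots) is given,
    the decoder, the state embeddings and the ζ output layer start in an
    identifiable mixture configuration: m_k sit at scaled latent corners,
    f(m_k) equals the anchor profile of state k, and ζ_μ(k, x) = m_k with
    zero spot dependence — so the likelihood informs the proportions from
    the first step instead of locking onto an arbitrary head labeling.
    """
    D, Hd = cfg.D_z, cfg.hidden
    inv_softplus = lambda y: np.log(np.expm1(y))
    def mlp(prefix, n_in, n_out):
        return {
            f"{prefix}1W": Tensor(kaiming_normal(rng, n_in, Hd),
                                  requires_grad=True),
            f"{prefix}1b": Tensor(np.zeros(Hd), requires_grad=True),
            f"{prefix}2W": Tensor(kaiming_normal(rng, Hd, n_out),
                                  requires_grad=True),
            f"{prefix}2b": Tensor(np.zeros(n_out), requires_grad=True),
        }
    p: dict[str, Tensor] = {
        # decoder f: single linear layer + softmax
        "Wf": Tensor(kaiming_normal(rng, D, G), requires_grad=True),
        "bf": Tensor(np.zeros(G), requires_grad=True),
        # q(u_k) = N(m_k, v_k)
        "m": Tensor(rng.standard_normal((K, D)) * 0.1, requires_grad=True),
        "v_raw": Tensor(np.full((K, D), inv_softplus(1.0)), requires_grad=True),
        # heterogeneity σ_k (variance), dispersion θ_g
        "sigma_raw": Tensor(np.full((K, 1), inv_softplus(1.0)),
                            requires_grad=True),
        "theta_raw": Tensor(np.full(G, inv_softplus(cfg.theta_init)),
                            requires_grad=True),
    }
    p.update(mlp("gam", G, K))            # proportion encoder γ
    p.update(mlp("lam", G, 2))            # library encoder λ
    p.update(mlp("zet", G, 2 * K * D))    # state-wise latent encoder ζ
    if anchor_logprof is not None:
        scale = 2.0
        m0 = np.zeros((K, D))
        for k in range(K):
            m0[k, k % D] = scale
        bf0 = anchor_logprof.mean(axis=0)
        Wf0 = np.zeros((D, G))
        for k in range(K):
            Wf0[k % D] += (anchor_logprof[k] - bf0) / scale
        p["m"] = Tensor(m0, requires_grad=True)
        p["Wf"] = Tensor(Wf0, requires_grad=True)
        p["bf"] = Tensor(bf0.copy(), requires_grad=True)
        p["zet2W"] = Tensor(np.zeros((Hd, 2 * K * D)), requires_grad=True)
        bz = np.empty((2, K, D))
        bz[0] = m0
        bz[1] = inv_softplus(1.0)
        p["zet2b"] = Tensor(bz.ravel(), requires_grad=True)
    if patch_dim is not None:
        p.update({
            # image encoder ξ: single layer (μ, σ)
            "Wxi": Tensor(kaiming_normal(rng, patch_dim, 2 * D),
                          requires_grad=True),
            "bxi": Tensor(np.zeros(2 * D), requires_grad=True),
            # image decoders g_μ, g_σ: linear + batch norm
            "Wgm": Tensor(kaiming_normal(rng, D, patch_dim), requires_grad=True),
            "bgm": Tensor(np.zeros(patch_dim), requires_grad=True),
            "bn_gm_g": Tensor(np.ones(patch_dim), requires_grad=True),
            "bn_gm_b": Tensor(np.zeros(patch_dim), requires_grad=True),
            "Wgs": Tensor(kaiming_normal(rng, D, patch_dim), requires_grad=True),
            "bgs": Tensor(np.zeros(patch_dim), requires_grad=True),
            "bn_gs_g": Tensor(np.ones(patch_dim), requires_grad=True),
            "bn_gs_b": Tensor(np.zeros(patch_dim), requires_grad=True),
        })
    return p


def _batchnorm(t: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    mu = t.mean(axis=0, keepdims=True)
    var = ((t - mu) ** 2).mean(axis=0, keepdims=True)
    return gamma * ((t - mu) / (var + 1e-5).sqrt()) + beta


# ---------------------------------------------------------------------------
# encoders (Tensor versions and deterministic numpy twins)


def _feature_stats(counts: np.ndarray):
    """Per-gene mean/sd of log1p counts, for standardized encoder inputs."""
    lx = np.log1p(counts.astype(np.float64))
    mu = lx.mean(axis=0)
    sd = lx.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def _features(counts: np.ndarray, stats=None) -> np.ndarray:
    """Featurization feeding the encoders (the likelihood sees raw x):
    log1p counts, standardized per gene when training stats are given."""
    lx = np.log1p(counts.astype(np.float64))
    if stats is None:
        return lx
    mu, sd = stats
    return (lx - mu) / sd


def _mlp_t(p, prefix, xf: Tensor) -> Tensor:
    return relu(xf @ p[f"{prefix}1W"] + p[f"{prefix}1b"]) \
        @ p[f"{prefix}2W"] + p[f"{prefix}2b"]


def _mlp_np(p, prefix, xf: np.ndarray) -> np.ndarray:
    h = np.maximum(xf @ p[f"{prefix}1W"].data + p[f"{prefix}1b"].data, 0.0)
    return h @ p[f"{prefix}2W"].data + p[f"{prefix}2b"].data


def _np_softmax(logits: np.ndarray) -> np.ndarray:
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _encode_gamma_np(p, xf: np.ndarray) -> np.ndarray:
    return _np_softmax(_mlp_np(p, "gam", xf))


def _encode_zeta_np(p, xf: np.ndarray, K: int, D: int):
    h = _mlp_np(p, "zet", xf).reshape(xf.shape[0], 2, K, D)
    return h[:, 0], np.logaddexp(0.0, h[:, 1]) + _VAR_FLOOR


def _encode_lambda_np(p, xf: np.ndarray, log_lib: np.ndarray):
    h = _mlp_np(p, "lam", xf)
    return h[:, 0] + log_lib, np.logaddexp(0.0, h[:, 1]) + _VAR_FLOOR


# ---------------------------------------------------------------------------
# ELBOs


def expression_elbo(counts: np.ndarray, priors_A: np.ndarray,
                    log_lib_prior: np.ndarray, p: dict[str, Tensor],
                    cfg: GenerativeConfig, rng: np.random.Generator, *,
                    n_total: int | None = None, recon_weight: float = 1.0,
                    features: np.ndarray | None = None,
                    _shared: dict | None = None):
    """Five-term ELBO of the expression view for one batch of spots.

    Returns ``(objective, terms)``: `terms` holds each per-spot-mean term
    (reconstruction, kl_z, kl_c, kl_l, kl_u) and the unweighted `elbo`;
    `objective` applies `recon_weight` to the reconstruction (the training
    warm-up), so at weight 1 it equals the ELBO. Reconstruction and the
    mixture-KL expectation use one reparameterized Monte Carlo sample
    (pathwise for Gaussians, implicit gamma for the Dirichlet); the
    Dirichlet and Gaussian KLs are closed form.
    """
    S, G = counts.shape
    K, D = priors_A.shape[1], cfg.D_z
    n_total = n_total or S
    xf = Tensor(_features(counts) if features is None else features)
    x = Tensor(counts.astype(np.float64))

    gam = softmax(_mlp_t(p, "gam", xf), axis=1)
    a_q = cfg.alpha * gam
    kl_c = _kl_dirichlet(a_q, cfg.alpha * priors_A).mean()

    # c ~ q(c|x) by pathwise gamma reparameterization
    g = gamma_rsample(a_q, rng)
    c = g / g.sum(axis=1, keepdims=True)

    # u ~ q(u), closed-form KL against N(0, u_prior_var)
    v = softplus(p["v_raw"]) + _VAR_FLOOR
    kl_u = _kl_normal(p["m"], v, 0.0, cfg.u_prior_var).sum() / n_total
    u = normal_rsample(p["m"], v, rng)

    # structured mixture posterior on z and its KL to p(z|c,u;σ)
    h = _mlp_t(p, "zet", xf).reshape(S, 2, K, D)
    z_mu_k = h[:, 0]
    z_var_k = softplus(h[:, 1]) + _VAR_FLOOR
    cw = c.reshape(S, K, 1)
    q_mu = (cw * z_mu_k).sum(axis=1)
    q_var = (cw * z_var_k).sum(axis=1)
    sigma = softplus(p["sigma_raw"]) + _VAR_FLOOR    # (K, 1) variances
    p_mu = c @ u
    p_var = c @ sigma
    kl_z = _kl_normal(q_mu, q_var, p_mu, p_var).sum(axis=1).mean()

    z = normal_rsample(q_mu, q_var, rng)

    # library
    hl = _mlp_t(p, "lam", xf)
    l_mu = hl[:, 0:1] + Tensor(log_lib_prior[:, None])
    l_var = softplus(hl[:, 1:2]) + _VAR_FLOOR
    kl_l = _kl_normal(l_mu, l_var, Tensor(log_lib_prior[:, None]),
                      cfg.lib_prior_sd ** 2).sum(axis=1).mean()
    log_l = normal_rsample(l_mu, l_var, rng)

    # NB reconstruction
    theta = softplus(p["theta_raw"]) + _VAR_FLOOR
    log_probs = log_softmax(z @ p["Wf"] + p["bf"], axis=1)
    mean_x = log_l.exp() * log_probs.exp() + 1e-10
    recon = _nb_log_pmf_t(x, mean_x, theta).sum(axis=1).mean()

    elbo = recon - kl_z - kl_c - kl_l - kl_u
    objective = recon_weight * recon - kl_z - kl_c - kl_l - kl_u
    terms = {"reconstruction": recon, "kl_z": kl_z, "kl_c": kl_c,
             "kl_l": kl_l, "kl_u": kl_u, "elbo": elbo}
    if _shared is not None:
        _shared.update(c=c, u=u, sigma=sigma, q_mu=q_mu, q_var=q_var,
                       log_l=log_l, xf=xf, x=x, theta=theta)
    return objective, terms


def _gaussian_loglik(y: Tensor, mu: Tensor, var: Tensor) -> Tensor:
    return -0.5 * (np.log(2.0 * np.pi) + var.log() + (y - mu) ** 2 / var)


def _decode_image(p, z: Tensor):
    mu = _batchnorm(z @ p["Wgm"] + p["bgm"], p["bn_gm_g"], p["bn_gm_b"])
    var = softplus(_batchnorm(z @ p["Wgs"] + p["bgs"],
                              p["bn_gs_g"], p["bn_gs_b"])) + _VAR_FLOOR
    return mu, var


def joint_elbo(counts: np.ndarray, patches_flat: np.ndarray,
               priors_A: np.ndarray, log_lib_prior: np.ndarray,
               p: dict[str, Tensor], cfg: GenerativeConfig,
               rng: np.random.Generator, *, n_total: int | None = None,
               recon_weight: float = 1.0,
               features: np.ndarray | None = None):
    """Information-bottleneck objective with histology integration.

    total = L_joint + a * (expression-view ELBO + histology-view ELBO); the
    joint term fuses the expression and image posteriors on z by a product
    of experts and reconstructs both views; the same conditional prior
    p(z|c,u;σ) appears in every KL. Returns ``(objective, terms)``;
    ``terms['elbo']`` is the unweighted total.
    """
    shared: dict = {}
    expr_obj, terms = expression_elbo(
        counts, priors_A, log_lib_prior, p, cfg, rng,
        n_total=n_total, recon_weight=recon_weight, features=features,
        _shared=shared)
    expr_elbo_t = terms["elbo"]
    yf = Tensor(patches_flat)
    D = cfg.D_z

    # PoE posterior on z
    hx = yf @ p["Wxi"] + p["bxi"]
    xi_mu, xi_var = hx[:, :D], softplus(hx[:, D:]) + _VAR_FLOOR
    poe_mu, poe_var = poe_combine(shared["q_mu"], shared["q_var"],
                                  xi_mu, xi_var)
    c, u, sigma = shared["c"], shared["u"], shared["sigma"]
    p_mu, p_var = c @ u, c @ sigma

    z_joint = normal_rsample(poe_mu, poe_var, rng)
    kl_z_joint = _kl_normal(poe_mu, poe_var, p_mu, p_var).sum(axis=1).mean()

    log_probs = log_softmax(z_joint @ p["Wf"] + p["bf"], axis=1)
    mean_x = shared["log_l"].exp() * log_probs.exp() + 1e-10
    recon_x_joint = _nb_log_pmf_t(shared["x"], mean_x,
                                  shared["theta"]).sum(axis=1).mean()
    gm, gv = _decode_image(p, z_joint)
    recon_y_joint = _gaussian_loglik(yf, gm, gv).sum(axis=1).mean()
    L_joint = recon_x_joint + recon_y_joint - kl_z_joint
    L_joint_obj = (recon_weight * (recon_x_joint + recon_y_joint)
                   - kl_z_joint)

    # histology-view marginal ELBO (c taken from the expression encoder)
    z_img = normal_rsample(xi_mu, xi_var, rng)
    gm2, gv2 = _decode_image(p, z_img)
    recon_y = _gaussian_loglik(yf, gm2, gv2).sum(axis=1).mean()
    kl_z_img = _kl_normal(xi_mu, xi_var, p_mu, p_var).sum(axis=1).mean()
    img_elbo = recon_y - kl_z_img
    img_obj = recon_weight * recon_y - kl_z_img

    total = L_joint + cfg.ib_weight * (expr_elbo_t + img_elbo)
    objective = L_joint_obj + cfg.ib_weight * (expr_obj + img_obj)
    terms = dict(terms)
    terms.update({"joint": L_joint, "expression_elbo": expr_elbo_t,
                  "histology_elbo": img_elbo, "elbo": total})
    return objective, terms


# ---------------------------------------------------------------------------
# training


def _reconstruction_loss(data: SpotDataset, priors: PriorBundle,
                         p: dict[str, Tensor], cfg: GenerativeConfig,
                         feat_stats=None) -> float:
    """Deterministic negative NB log-likelihood at the posterior means."""
    xf = _features(data.counts, feat_stats)
    c = _encode_gamma_np(p, xf)
    K, D = c.shape[1], cfg.D_z
    z_mu_k, _ = _encode_zeta_np(p, xf, K, D)
    z = np.einsum("sk,skd->sd", c, z_mu_k)
    l_mu, _ = _encode_lambda_np(p, xf, np.log(priors.lib_prior))
    l = np.exp(l_mu)[:, None]
    probs = decode_mean_expression(z, (p["Wf"].data, p["bf"].data))
    theta = np.logaddexp(0.0, p["theta_raw"].data) + _VAR_FLOOR
    ll = nb_log_pmf(data.counts, l * probs + 1e-10, theta)
    return float(-ll.sum(axis=1).mean())


def train(data: SpotDataset, priors: PriorBundle,
          patches: PatchSet | None = None,
          cfg: GenerativeConfig | None = None) -> VariationalState:
    """Fit the model with independent restarts; keep the best reconstruction.

    Restart i uses seed ``cfg.seed + i``; each runs `cfg.epochs` epochs of
    minibatch Adam with exponential learning-rate decay and the likelihood
    warm-up ramp. The restart with the lowest deterministic negative
    reconstruction log-likelihood wins; a restart whose loss turns
    non-finite is aborted and recorded as failed.
    """
    cfg = cfg or GenerativeConfig()
    K = priors.A.shape[1]
    if cfg.K and cfg.K != K:
        raise ValueError("cfg.K disagrees with the prior bundle")
    cfg.K = K
    if data.n_spots != priors.A.shape[0]:
        raise ValueError("priors were built from a different dataset")
    if cfg.poe_enabled and patches is None:
        raise ValueError("poe_enabled requires patches")
    use_poe = cfg.poe_enabled and patches is not None
    patches_flat = patches.flattened() if use_poe else None
    log_lib = np.log(priors.lib_prior)
    S, G = data.counts.shape
    warm_epochs = max(1, int(round(cfg.warmup_frac * cfg.epochs)))
    feat_stats = _feature_stats(data.counts)
    xf_all = _features(data.counts, feat_stats)
    # anchor-spot log profiles seed the decoder and state embeddings
    prof = np.vstack([
        data.counts[priors.anchors[:, k]].mean(axis=0) + 0.5
        for k in range(K)])
    anchor_logprof = np.log(prof / prof.sum(axis=1, keepdims=True))

    best: VariationalState | None = None
    best_recon = np.inf
    restart_traces: list[list[float]] = []
    restart_recon: list[float] = []
    for r in range(cfg.restarts):
        rng = np.random.default_rng(cfg.seed + r)
        p = _init_params(G, K, cfg, rng,
                         patch_dim=(patches_flat.shape[1] if use_poe else None),
                         anchor_logprof=anchor_logprof)
        opt = Adam(list(p.values()), lr=cfg.lr, lr_decay=cfg.lr_decay)
        trace: list[float] = []
        failed = False
        for ep in range(cfg.epochs):
            w = min(1.0, (ep + 1) / warm_epochs)
            perm = rng.permutation(S)
            batches = np.array_split(perm, int(np.ceil(S / cfg.batch_size)))
            epoch_elbo = 0.0
            for idx in batches:
                opt.zero_grad()
                if use_poe:
                    obj, terms = joint_elbo(
                        data.counts[idx], patches_flat[idx], priors.A[idx],
                        log_lib[idx], p, cfg, rng, n_total=S, recon_weight=w,
                        features=xf_all[idx])
                else:
                    obj, terms = expression_elbo(
                        data.counts[idx], priors.A[idx], log_lib[idx],
                        p, cfg, rng, n_total=S, recon_weight=w,
                        features=xf_all[idx])
                loss = -obj
                if not np.isfinite(loss.data):
                    failed = True
                    break
                loss.backward()
                opt.step()
                epoch_elbo += terms["elbo"].item() * len(idx) / S
            if failed:
                break
            trace.append(epoch_elbo)
            opt.decay_lr()
        restart_traces.append(trace)
        if failed:
            restart_recon.append(float("inf"))
            continue
        recon = _reconstruction_loss(data, priors, p, cfg, feat_stats)
        restart_recon.append(recon)
        if recon < best_recon:
            best_recon = recon
            best = VariationalState(params=p, cfg=cfg, priors=priors,
                                    elbo_trace=trace, feat_stats=feat_stats,
                                    trained=True)
    if best is None:
        raise RuntimeError(
            "all restarts diverged (non-finite loss); epochs completed "
            f"per restart: {[len(t) for t in restart_traces]}")
    best.restart_traces = restart_traces
    best.restart_recon = restart_recon
    return best


# ---------------------------------------------------------------------------
# inference


def infer(data: SpotDataset, patches: PatchSet | None,
          state: VariationalState) -> DeconvolutionResult:
    """Deterministic posterior summaries (means only, no sampling).

    c is the variational mean of q(c|x; α) — the normalized α γ(x), i.e.
    γ(x) itself; z is the mixture posterior mean (fused with the image view
    when patches are given and the model was trained with them); l is the
    exponential of the posterior mean log-library.
    """
    if not state.trained:
        raise ValueError("model has not been trained")
    p, cfg, priors = state.params, state.cfg, state.priors
    xf = _features(data.counts, state.feat_stats)
    K, D = priors.A.shape[1], cfg.D_z

    c = _encode_gamma_np(p, xf)
    z_mu_k, z_var_k = _encode_zeta_np(p, xf, K, D)
    z_mu = np.einsum("sk,skd->sd", c, z_mu_k)
    z_var = np.einsum("sk,skd->sd", c, z_var_k)
    recon_img = None
    if patches is not None and "Wxi" in p:
        yf = patches.flattened()
        hx = yf @ p["Wxi"].data + p["bxi"].data
        xi_mu, xi_var = hx[:, :D], np.logaddexp(0.0, hx[:, D:]) + _VAR_FLOOR
        z_mu, z_var = poe_combine(z_mu, z_var, xi_mu, xi_var)
        gm = z_mu @ p["Wgm"].data + p["bgm"].data
        mu_bn = gm.mean(axis=0, keepdims=True)
        var_bn = gm.var(axis=0, keepdims=True)
        recon_img = (p["bn_gm_g"].data * (gm - mu_bn) / np.sqrt(var_bn + 1e-5)
                     + p["bn_gm_b"].data)

    l_mu, _ = _encode_lambda_np(p, xf, np.log(priors.lib_prior))
    l = np.exp(l_mu)
    probs = decode_mean_expression(z_mu, (p["Wf"].data, p["bf"].data))
    state_expr = np.vstack([
        predict_state_expression(state, k, data) for k in range(K)])
    return DeconvolutionResult(
        c=c, z=z_mu, l=l, recon_expr=l[:, None] * probs,
        state_expr=state_expr, spot_ids=list(data.spot_ids),
        state_names=list(priors.state_names), recon_img=recon_img)


def predict_state_expression(state: VariationalState, k: int,
                             data: SpotDataset) -> np.ndarray:
    """Expression profile of one cell state (sums to 1).

    The proportion vector is forced to one-hot(k), so the latent collapses
    to the state-specific head ζ_μ(k, ·); it is evaluated at the average
    over state k's anchor spots and decoded through f.
    """
    p, cfg, priors = state.params, state.cfg, state.priors
    K, D = priors.A.shape[1], cfg.D_z
    if not 0 <= k < K:
        raise ValueError(f"state index {k} out of range")
    anchors = priors.anchors[:, k]
    xf = _features(data.counts[anchors], state.feat_stats)
    z_mu_k, _ = _encode_zeta_np(p, xf, K, D)
    z_k = z_mu_k[:, k, :].mean(axis=0)
    return decode_mean_expression(z_k, (p["Wf"].data, p["bf"].data))
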