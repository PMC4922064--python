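"""Simple diagnostic plots: coverage track, MAF histogram, spectrum bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io_formats import CallTable
from .stats import SUBSTITUTIONS, CoverageProfile, MutationSpectrum


def plot_coverage(profile: CoverageProfile, path: str) -> None:
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.fill_between(range(1, len(profile.depth) + 1), profile.depth, step="mid", alpha=0.7)
    ax.axhline(profile.ratio_threshold, color="red", lw=0.8, ls="--")
    ax.set_xlabel("mtDNA position")
    ax.set_ylabel("depth")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_maf_histogram(calls: CallTable, path: str) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(calls.df["minor_fraction"].astype(float), bins=20, range=(0, 0.5))
    ax.set_xlabel("minor allele fraction")
    ax.set_ylabel("heteroplasmies")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spectrum(spectrum: MutationSpectrum, path: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(SUBSTITUTIONS, [spectrum.counts.get(s, 0) for s in SUBSTITUTIONS])
    ax.set_ylabel("count")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
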