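"""Minimal textbook VMD used as an independent test oracle.

A direct transcription of the canonical ADMM update scheme for
variational mode decomposition: for each mode, a Wiener-filter update of
the analytic spectrum around its centre frequency, a power-weighted
centre-frequency update, and a dual ascent on the reconstruction
constraint.  Deliberately plain -- no mirror extension, no accumulator
tricks, no clustering -- so that agreement with the package's engine is a
meaningful cross-check rather than a tautology.
"""

import numpy as np


def reference_vmd(signal, alpha, tau, n_modes, tol=1e-7, max_iter=500,
                  init_omegas=None):
    """Return (modes, center_frequencies_cycles_per_sample)."""
    f = np.asarray(signal, dtype=float)
    n = f.size
    freqs = np.fft.fftshift(np.fft.fftfreq(n))
    f_hat = np.fft.fftshift(np.fft.fft(f))
    f_hat_plus = np.where(freqs >= 0, f_hat, 0.0)

    if init_omegas is None:
        omega = np.linspace(0.0, 0.5, n_modes + 2)[1:-1].astype(float)
    else:
        omega = np.array(init_omegas, dtype=float)
    u_hat = np.zeros((n_modes, n), dtype=complex)
    lam = np.zeros(n, dtype=complex)

    for _ in range(max_iter):
        u_prev = u_hat.copy()
        for k in range(n_modes):
            others = u_hat.sum(axis=0) - u_hat[k]
            u_hat[k] = (f_hat_plus - others - lam / 2.0) / (
                1.0 + 2.0 * alpha * (freqs - omega[k]) ** 2)
            num = np.sum(freqs[freqs >= 0] * np.abs(u_hat[k][freqs >= 0]) ** 2)
            den = np.sum(np.abs(u_hat[k][freqs >= 0]) ** 2)
            if den > 0:
                omega[k] = num / den
        lam = lam + tau * (u_hat.sum(axis=0) - f_hat_plus)
        change = sum(
            np.sum(np.abs(u_hat[k] - u_prev[k]) ** 2)
            / max(np.sum(np.abs(u_prev[k]) ** 2), 1e-30)
            for k in range(n_modes)
        )
        if change < tol:
            break

    modes = np.empty((n_modes, n))
    for k in range(n_modes):
        spectrum = np.zeros(n, dtype=complex)
        pos = freqs >= 0
        spectrum[pos] = u_hat[k][pos]
        full = np.fft.ifftshift(spectrum)
        # hermitian completion for a real mode
        time_mode = np.fft.ifft(full)
        modes[k] = 2.0 * np.real(time_mode) - np.real(full[0]) / n
    order = np.argsort(omega)
    return modes[order], np.abs(omega[order])
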