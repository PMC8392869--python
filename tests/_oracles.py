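"""Independent straight-line recomputations used as test oracles."""

import numpy as np

from polyptile import features as F


def _oracle_antecedents(pixels, cfg=None):
    """Independent straight-line recomputation of the 99 antecedents."""
    import skimage.feature as skf
    from scipy import ndimage as ndi

    cfg = cfg or F.FeatureConfig()
    s = 1 / np.sqrt(2)

    def haar(a):
        lo = s * (a[:, 0::2] + a[:, 1::2])
        hi = s * (-a[:, 0::2] + a[:, 1::2])
        ll = s * (lo.T[:, 0::2] + lo.T[:, 1::2])
        lh = s * (-lo.T[:, 0::2] + lo.T[:, 1::2])
        hl = s * (hi.T[:, 0::2] + hi.T[:, 1::2])
        hh = s * (-hi.T[:, 0::2] + hi.T[:, 1::2])
        return ll.T, lh.T, hl.T, hh.T

    def entropies(ch):
        p = ch.ravel() / ch.sum()
        p = p[p > 0]
        s0 = np.log(p.size)
        s1 = float(-(p * np.log(p)).sum())
        s2 = -np.log((p ** 2).sum())
        return s1 - s2, s2 - s0

    def edge(ch):
        if ch.std() == 0:
            return 0.0
        sm = ndi.gaussian_filter(ch, cfg.canny_sigma, mode="reflect")
        mag = np.hypot(ndi.sobel(sm, 1, mode="reflect"),
                       ndi.sobel(sm, 0, mode="reflect"))
        e = skf.canny(ch, sigma=cfg.canny_sigma,
                      low_threshold=cfg.canny_low * mag.max(),
                      high_threshold=cfg.canny_high * mag.max())
        return e.sum() / ch.size

    def fifteen(chans):
        out = []
        for ch in chans:
            out += [ch.mean(), ch.std()]
        out += [edge(ch) for ch in chans]
        for ch in chans:
            out += list(entropies(ch))
        return out

    chans = [pixels[:, :, k] for k in range(3)]
    vals = fifteen(chans)
    bands = [haar(ch) for ch in chans]
    for b in range(4):
        band_chans = [np.abs(bands[k][b]) if b else bands[k][b]
                      for k in range(3)]
        vals += fifteen(band_chans)
    for ch in chans:
        padded = np.pad(ch, 1, mode="symmetric")
        t = ch.shape[0]
        gx = np.zeros_like(ch)
        gy = np.zeros_like(ch)
        for i in range(t):
            for j in range(t):
                win = padded[i:i + 3, j:j + 3]
                gx[i, j] = (win * F.SOBEL_X).sum()
                gy[i, j] = (win * F.SOBEL_Y).sum()
        mag = np.hypot(gx, gy)
        direction = np.arctan2(gy, gx)
        direction[mag < 1e-12] = 0.0
        ch_grads = [mag, direction, gx, gy]
        vals.append(ch_grads)
    grads = vals[-3:]
    vals = vals[:-3]
    for q in range(4):
        for c in range(3):
            vals += [grads[c][q].mean(), grads[c][q].std()]
    return np.array(vals)
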