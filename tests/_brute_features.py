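"""Slow per-window reference implementation for validating ith3d.features."""
import numpy as np
from itertools import product

def brute_window_features(w, bin_width, shape):
    w = np.asarray(w, float).reshape(shape)
    flat = w.ravel()
    n = flat.size
    g = np.floor((flat - flat.min()) / bin_width).astype(int) + 1
    gv = g.reshape(shape)
    pos = list(product(*[range(s) for s in shape]))
    out = {}
    # first order
    mu = flat.mean(); var = flat.var(); sd = np.sqrt(var)
    out['firstorder_mean'] = mu
    out['firstorder_median'] = np.percentile(flat, 50)
    out['firstorder_minimum'] = flat.min()
    out['firstorder_maximum'] = flat.max()
    out['firstorder_range'] = flat.max() - flat.min()
    out['firstorder_variance'] = var
    out['firstorder_skewness'] = ((flat-mu)**3).mean()/sd**3 if sd>1e-12 else 0.0
    out['firstorder_kurtosis'] = ((flat-mu)**4).mean()/sd**4 if sd>1e-12 else 0.0
    out['firstorder_energy'] = (flat**2).sum()
    out['firstorder_rms'] = np.sqrt((flat**2).mean())
    out['firstorder_mad'] = np.abs(flat-mu).mean()
    out['firstorder_iqr'] = np.percentile(flat,75)-np.percentile(flat,25)
    out['firstorder_p10'] = np.percentile(flat,10)
    out['firstorder_p90'] = np.percentile(flat,90)
    cnt = {}
    for x in g: cnt[x] = cnt.get(x,0)+1
    p = np.array(list(cnt.values()))/n
    out['firstorder_entropy'] = -(p*np.log2(p)).sum()
    out['firstorder_uniformity'] = (p**2).sum()
    # ordered symmetric voxel pairs (all distinct position pairs, both directions)
    pairs = []
    for i in range(n):
        for j in range(n):
            if i != j:
                pairs.append((g[i], g[j]))
    pa = np.array([a for a,b in pairs], float); pb = np.array([b for a,b in pairs], float)
    diff = pa-pb
    glcm = {}
    for a,b in pairs: glcm[(a,b)] = glcm.get((a,b),0)+1
    P = np.array(list(glcm.values()))/len(pairs)
    mu_p = pa.mean(); var_p = ((pa-mu_p)**2).mean()
    ac = (pa*pb).mean()
    out['glcm_contrast'] = (diff**2).mean()
    out['glcm_dissimilarity'] = np.abs(diff).mean()
    out['glcm_inverse_difference'] = (1/(1+np.abs(diff))).mean()
    out['glcm_idm'] = (1/(1+diff**2)).mean()
    out['glcm_correlation'] = (ac-mu_p**2)/var_p if var_p>1e-12 else 0.0
    out['glcm_joint_average'] = mu_p
    out['glcm_autocorrelation'] = ac
    out['glcm_cluster_shade'] = ((pa+pb-2*mu_p)**3).mean()
    out['glcm_cluster_prominence'] = ((pa+pb-2*mu_p)**4).mean()
    out['glcm_joint_energy'] = (P**2).sum()
    out['glcm_joint_entropy'] = -(P*np.log2(P)).sum()
    out['glcm_max_probability'] = P.max()
    # GLRLM over all displacement directions (unique up to sign); window width 2
    # lines of length<=2: run of len2 if equal pair, else singleton runs
    dirs = set()
    for i in range(n):
        for j in range(n):
            if i < j:
                d = tuple(np.array(pos[j])-np.array(pos[i]))
                dirs.add(d)
    runs = []  # (gray, length)
    for d in dirs:
        covered = set()
        for i in range(n):
            j_pos = tuple(np.array(pos[i])+np.array(d))
            if j_pos in pos:
                j = pos.index(j_pos)
                covered.add(i); covered.add(j)
                if g[i]==g[j]: runs.append((g[i],2))
                else: runs.append((g[i],1)); runs.append((g[j],1))
        for i in range(n):
            if i not in covered: runs.append((g[i],1))
    Nr = len(runs)
    rl = np.array([l for _,l in runs], float); rg = np.array([q for q,_ in runs], float)
    out['glrlm_sre'] = (1/rl**2).sum()/Nr
    out['glrlm_lre'] = (rl**2).sum()/Nr
    cg = {}
    for q,_ in runs: cg[q]=cg.get(q,0)+1
    out['glrlm_gln'] = sum(v**2 for v in cg.values())/Nr
    out['glrlm_glnn'] = out['glrlm_gln']/Nr
    cl = {}
    for _,l in runs: cl[l]=cl.get(l,0)+1
    out['glrlm_rln'] = sum(v**2 for v in cl.values())/Nr
    out['glrlm_rlnn'] = out['glrlm_rln']/Nr
    out['glrlm_rp'] = Nr/(n*len(dirs))
    out['glrlm_glv'] = (rg**2).mean()-(rg.mean())**2
    cgl = {}
    for q,l in runs: cgl[(q,l)] = cgl.get((q,l),0)+1
    pr = np.array(list(cgl.values()))/Nr
    out['glrlm_run_entropy'] = -(pr*np.log2(pr)).sum()
    out['glrlm_lglre'] = (1/rg**2).mean()
    out['glrlm_hglre'] = (rg**2).mean()
    # GLSZM: zones = connected same-level sets; all voxels mutually adjacent -> per-level
    zones = [(q, c) for q, c in cnt.items()]
    Nz = len(zones)
    zs = np.array([c for _,c in zones], float); zg = np.array([q for q,_ in zones], float)
    out['glszm_sae'] = (1/zs**2).sum()/Nz
    out['glszm_lae'] = (zs**2).sum()/Nz
    out['glszm_zone_percentage'] = Nz/n
    out['glszm_zone_entropy'] = np.log2(Nz)
    out['glszm_zone_variance'] = (zs**2).mean()-(zs.mean())**2
    out['glszm_lglze'] = (1/zg**2).sum()/Nz
    out['glszm_hglze'] = (zg**2).sum()/Nz
    # GLDM: dependence = 1 + count of equal-level other voxels (all adjacent)
    d_of = np.array([1 + sum(1 for j in range(n) if j!=i and g[j]==g[i]) for i in range(n)], float)
    out['gldm_sde'] = (1/d_of**2).mean()
    out['gldm_lde'] = (d_of**2).mean()
    cd = {}
    for d in d_of: cd[d]=cd.get(d,0)+1
    out['gldm_dn'] = sum(v**2 for v in cd.values())/n
    out['gldm_dnn'] = out['gldm_dn']/n**2
    cjoint = {}
    for i in range(n): cjoint[(g[i],d_of[i])]=cjoint.get((g[i],d_of[i]),0)+1
    pj = np.array(list(cjoint.values()))/n
    out['gldm_de'] = -(pj*np.log2(pj)).sum()
    out['gldm_gln'] = sum(v**2 for v in cnt.values())/n
    out['gldm_dv'] = d_of.var()
    out['gldm_lgle'] = (1/g.astype(float)**2).mean()
    out['gldm_hgle'] = (g.astype(float)**2).mean()
    # NGTDM: all others are neighbours
    gf = g.astype(float)
    s = {}
    for i in range(n):
        Ai = (gf.sum()-gf[i])/(n-1)
        s[g[i]] = s.get(g[i],0)+abs(gf[i]-Ai)
    levels = sorted(cnt)
    pi = {q: cnt[q]/n for q in levels}
    Ng = len(levels)
    sum_ps = sum(pi[q]*s[q] for q in levels)
    sum_s = sum(s.values())
    out['ngtdm_coarseness'] = min(1/sum_ps if sum_ps>1e-12 else 1e6, 1e6)
    if Ng>1:
        c = sum(pi[a]*pi[b]*(a-b)**2 for a in levels for b in levels)
        out['ngtdm_contrast'] = c/(Ng*(Ng-1))*(sum_s/n)
        den_b = sum(abs(a*pi[a]-b*pi[b]) for a in levels for b in levels if a!=b)
        out['ngtdm_busyness'] = sum_ps/den_b if den_b>1e-12 else 0.0
        out['ngtdm_complexity'] = sum(abs(a-b)*(pi[a]*s[a]+pi[b]*s[b])/(pi[a]+pi[b])
                                      for a in levels for b in levels if a!=b)/n
        out['ngtdm_strength'] = (sum((pi[a]+pi[b])*(a-b)**2 for a in levels for b in levels if a!=b)
                                 / sum_s if sum_s>1e-12 else 0.0)
    else:
        out['ngtdm_contrast']=0.0; out['ngtdm_busyness']=0.0
        out['ngtdm_complexity']=0.0; out['ngtdm_strength']=0.0
    return out
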