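gene	chain	cdr1	cdr2	cdr2_5
TRBV2	beta	PTNSIW	ADIAM	TKNC
TRBV4-1	beta	YSPYWL	CLFMY	FQNPP
TRBV5-1	beta	GAWSE	GCKGHR	FQDNIF
TRBV6-1	beta	VVWYAK	PHHKR	FGTKYR
TRBV7-2	beta	FIQMW	QPDHF	HRFDR
TRBV9	beta	LDQSG	YAFYTMM	YQHCW
TRBV11-2	beta	GTWWY	EQHYYD	ASHI
TRBV12-3	beta	MATNNP	RLMCYK	VIGYEY
TRBV15	beta	GGEAQK	DPPQSP	NRSI
TRBV18	beta	EWAQV	KYEPV	ESKPI
TRBV19	beta	EDFYA	KHYFKVA	ELSTV
TRBV20-1	beta	HDCPI	RRKMITI	IPHW
TRBV25-1	beta	MYGMN	YDFRYY	YTMGLQ
TRBV27	beta	REHIRG	EPWKF	YMCHA
TRBV28	beta	EFHGA	IFFMY	TPFLFA
TRBV29-1	beta	CKWCE	DALQYCT	QVGLS
TRBV30	beta	IRCNSC	TIIWNE	CAKH
TRAV1-2	alpha	RAYNV	GGQYVQ	AMPT
TRAV3	alpha	MICMQ	DEFLI	WDGKAL
TRAV8-1	alpha	EIRII	TQGEEI	HNHV
TRAV9-2	alpha	ITIGVM	GEIRIF	SLSPEA
TRAV12-1	alpha	TFEET	GETAVT	INWP
TRAV13-1	alpha	HPKYEN	NRNFSFF	FLPDW
TRAV17	alpha	NEPAV	PTHQMF	YHCEYR
TRAV19	alpha	RQSRK	RFRSTQ	SPWW
TRAV21	alpha	GAEYK	ENPYS	NVNC
TRAV22	alpha	HWVMF	PFFNP	LMAAWF
TRAV26-1	alpha	QMHSAL	CCMHHV	WKGCQ
TRAV27	alpha	CQYAK	VAICVW	HSWQS
TRAV29	alpha	DWHNTV	NGQGR	RYMGMR
TRAV35	alpha	GTDRPS	DNLATPN	FCKEYV
TRAV38-1	alpha	IVGKLE	HNYDQFN	WPMWWG
TRAV41	alpha	DFLSNC	GNWEAG	LGMIAC
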