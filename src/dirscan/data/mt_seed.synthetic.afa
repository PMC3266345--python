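>mt_seed_0
HENGGLVQSSLRFHPNLYGRWFIDMREVYIADFMDMTTNDHYQRFCVTGLIRCMADWVYE
RIFMHIHNRWIDCNVEARNPFSLHEHSNSEYYM
>mt_seed_1
GENGGLVQSSLRFHPNLYNRWFIDMREVYPPDNAWMKTNDCYQRFCPTGLIRCMADWMME
RISMHIHNCWIDCNVEKRNPFHLHEHSSSEYYM
>mt_seed_2
GENGGLVQSSLRFHPNLIGRWFIDFREVYIADNMWMKSIDHYQRFCPTLLIRCMADWVEE
RISMHVHNCWIDCNVENRNPFHLHEHSDSEAYM
>mt_seed_3
GENLGGVQSSKRFHPNLYGRWFIDMREVYIADNMKMKTMDHYQRDCPTGLIRCMADWVEE
RISMHIHNCWIDCNVEARWPFHHHEHANSEYYM
>mt_seed_4
GENGGLVQSSLRFHPNLYGRWFHDMRTVYIADNMWMKTNDHYQRFCPTGLVRIMADWVEE
LISMHIHGMWIDCNYEARNPRHLHEHSNSEYYM
>mt_seed_5
GENGGVVQSSLRFYPNLYGREFIDMREVYIADNMWMKTQDHYARTSATGLIRCMADWVEE
RISMHIHNCWIDCNVEARNPFHLHEHSNSEYYQ
>mt_seed_6
GENGGLVQSSLFFHPNLDGRWFIDMREVYIADSMWMDTNDHYQRFCPWGDIRCMADWVEE
RISMHIHNTSIDCNVDARNPFHLHEHSNSEYYM
>mt_seed_7
GENEGLVQSSLRFHPNYYGRPFIRMREVHRADNMWMKTNDHYQPFCPTGLIRCMADWVLE
RISMHIHNCWIDCNVEARNPMHLHEHSNSEYYM
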