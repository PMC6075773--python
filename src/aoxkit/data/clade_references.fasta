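>AOX1a
CTDYGFYFMLHMRQIFWDVYDIGPHITYMECARCDNYGILETVAAGLVIRQITFMFCWSA
RMCMIPYCPERMHLMTDRVEGKPYTALDPRTLCSLDFPTPHFARYTKMWRPETAGQCRVV
MLELVAPVDMMSECMDPHLVSLRKFPQSQANMHVVLNHAYVERSHLMVKQVYDGEKAYER
ALVMAVQKVFNIAYLTGYNISCNFANRVVWGLELFAYLEEEAGHYPMGTHHTRMNFPYFI
DMDYKPCNNEMGMANTHYNSDRTGIEGKHVVKWPLRADEAHHKWYKVWPHYWPSKAGRCF
AQPFPKKVSNTPTTHEHEALNFYTSDLDIMYNLHDMHRIR
>AOX1c
WEDYPKYFLPHMITIFEAVYFFGPKLTYSQCATVDNQCILETVAAGVNIRTTTFMFCWSA
RMCMIPYCPERMHLMTDRVEGKPYTALDPRTLCSLDVPTPHFARYTKMWRPETAGQCRVV
MLELVAPVDMMSECMDPHLVSLRKFPQSQANMHVVLNHAYVERSHLMVKQVYDGEKAYER
ALVMAVQKVFNIAYLTGYNVSCNFANRVVWGLELFAYLEEEAGHYPMGTHHTRMNFPYFI
DMDYKPCNNEMGMANTHYNSDRTGIEGKHVVKWPLRADEAHHKWYKVWPHYWPSKAGRCF
AQPFPKKVSNTPTTHEHEALNFYTSDLDIMYNLHDMHRIR
>AOX1e
WTHYPFLFLLRMIQWFEDDYFIIPKIMYSESATCYNQGELETVAAGVVRRTIWFMFCWSA
RMCMIPYCPERMHLMTDRVEGKPYTALDPRTLCAIDWPTPHFARYTKMWRPETAGQCRVV
MLELVAPVDMMSECADPHLVSLRKFPQSQANMHVVLNHAYVERSHLMVKQVYDGEKAYER
ALVMVVQKVFNIAYLTTYNASCNVANRMVWGLELFAYLEEEAGHYPMGTHHTRMNFPYFI
DMDYKPCNNEMGMANTHYNSDRTGIEGKHVVKWPLRADEAHHKWYKVWPHYWPSKAGRCF
AQPFPKKVSNTPTTHEHEALNFYTSDLDIMYNLHDMHRIR
>AOX1d
WTDIPFYPLLHTIQIAEDVFFIGKKITPSECVTCDCQGILETVAAPVVITTITAMFCWSA
RMCMIPYCPERMHLMTDRVEGKPYTALDPRVLCSLDVPRPHFARYTKMWRPETAGQSHVV
LLELVAPVDMMSECVDPHLVSLRKFPHSQANMHVVMNHAYVERSHLMVKQVYDGDKAWER
ALVMAAQKVFNIAYLTGYNISCNFANRFVWGLELFAYLEEEAGHYPMGTHHTRMNFPYFI
DMDYKPCNNEMGMANTHYNSDRTGIEGKHVVKWPLRADEAHHKWYKVWPHYWPSRAGRCF
AQPFPKKVSNTPTTHEHEALNFYTSDLDIMYNLHDMHRIR
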