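/root/pkg/testsoracles.py__init__.pytest_synth.pytest_preprocess.pytest_graph.pytest_pipeline_cli.pytest_stats.pytest_acceptance.pytest_connectivity.pyconftest.py      �   ����o�k�%D$�!?��         �   �����^�I�^T�!?��         �   ������ٲ�E�!?��         �   \����w����"�!?��         �   (����=$����˹!?��         �   ����	{1�E2��!?��          �   �������E7��!?��         �   �����oe*{�h�!?��          �   q���b�k��3�B�!?��         �   G����]A���ӹ!?��                                         �n7 aay!S�n7 aay!S��������� �   ��������
      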